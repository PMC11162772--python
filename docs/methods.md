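# Methods

## Read model

A library molecule is sequenced as a single high-accuracy long read with the
segment order `TSO — transcript — poly(A) tail — anchor — UMI(12) —
index(8)`, in either orientation. Parsing searches the read and its reverse
complement for the TSO (default `AAGCAGTGGTATCAACGCAGAGTACATGGG`, the
template-switch oligo with its riboguanosines read as G) and, downstream of
it, for the anchor (default `CGGAAGCAGTGGTATCAACGCAGAGT`, the constant
binding-oligo segment 5' of the UMI). Both probes allow one substitution by
default (`OligoLayout.max_probe_mismatch`), no indels: CCS-grade reads make
near-exact matching sufficient, and the sliding mismatch scan only runs
when an exact `str.find` fails. A read is kept iff the TSO is found in
exactly one orientation and the anchor follows it with at least
UMI + index bases to spare; otherwise it is rejected with a reason code
(`no_tso`, `chimera`, `no_anchor`, `truncated`) that the pipeline counts.
The anchor shares a 23-mer with the TSO (both derive from the same
template-switch sequence), so probe matching always uses the full probe
length, where they differ unambiguously.

Demultiplexing assigns a read to the unique sample whose 8-bp index is
within Hamming distance 1 (configurable) of the observed index; the sample
sheet is validated up front so that no two indices are within twice that
tolerance, making "unique" guaranteed rather than hoped for. UMI
deduplication keeps, per (sample, exact 12-mer UMI), the read with the
longest insert, ties broken by smallest read id. Mismatch-tolerant UMI
clustering is deliberately not the default: at CCS accuracy, 12-mer
sequencing errors are rare relative to the UMI space, and exact collapsing
is order-independent and idempotent.

## Tail calling

The tail of a clean read is the insert suffix that does not align to the
genome: `call_tail_softclip` takes the insert coordinate where the 3' soft
clip starts and returns everything after it, with the non-A residue count
and fraction. No rescue of tail bases absorbed into genomic A-runs is
attempted by default; the caller trusts the aligner's boundary.

`call_tail_suffix` is the alignment-free fallback: the longest suffix that
starts with an A and has A-fraction ≥ `min_a_frac` (default 0.8), empty if
shorter than `min_len` (default 5). Because a global fraction constraint
grows permissive for long tails, this heuristic is not used where better
information exists: spike-in reads are identified by their 3' barcode
(≤ 1 mismatch) and their tail is taken as the insert between the known
spike-in body sequence and the barcode, which recovers defined tail
lengths exactly even when the tail itself carries non-A residues.

Because "non-A usage" can be read per-residue or per-read, summaries emit
both: the per-read non-A fraction and, per gene, the fraction of reads with
at least one non-A residue.

## Gene assignment

The cleavage position of a read is the reference coordinate of its
3'-terminal aligned base (rightmost for `+`, leftmost for `-`); only primary
alignments are used and reads whose 3' soft clip is shorter than
`min_tail_len` (default 1 nt) are dropped — a molecule without a tail is not
evidence of polyadenylation. A read end is assigned to a gene when it falls
inside the merged-exon span extended 1000 nt downstream (configurable
`flank`; distal sites often lie past the annotated transcript end) on the
matching strand; ends inside two or more gene footprints are discarded
rather than arbitrated, ends in none are counted unassigned.

Annotation handling: exons of all transcripts of a gene are unioned
(overlapping *and* abutting intervals merge; the union is idempotent);
noncoding rows are skipped because the analysis is anchored on the stop
codon; when transcripts disagree, the stop codon of the transcript with the
most downstream CDS end in transcription direction is used — a
deterministic choice favouring the longest coding form. Distances to the
stop codon are genomic, not spliced: 3'-UTR poly(A) sites nearly always lie
in the terminal exon, where the two coincide. Classification into
proximal/distal for the shift test uses the absolute distance by default;
`apa_shift_test(absolute=False)` restricts "near" to the downstream side
for users who prefer the signed reading.

## Greedy site calling

Parameters (`ApaParams`), all configurable, defaults being the method's
operating point:

| parameter          | default | meaning                                        |
|--------------------|---------|------------------------------------------------|
| `depth_window`     | 5 nt    | centered window for candidate depth (±2 nt)    |
| `min_depth`        | 2 reads | windowed-depth floor for acceptance            |
| `min_site_spacing` | 15 nt   | accepted sites must be > this far apart        |
| `assign_radius`    | 10 bp   | read counts at a site when within this (incl.) |
| `stop_codon_cutoff`| 50 bp   | proximal/distal boundary for the shift test    |

Candidate depths are computed once from the full read set and are not
recomputed after each acceptance: the greedy step removes *candidates*, not
reads. A `recompute_depths` flag exists for sensitivity analysis. Three
tie/boundary conventions are fixed and tested: equal depths break to the
smaller genomic coordinate; "outside the 15-nt range" is strict
(distance ≤ 15 suppresses); "within 10 bp" is inclusive (|d| ≤ 10). A read
equidistant from two sites counts at the upstream one in transcription
direction. Genes with no accepted site are reported in the "0 sites"
category rather than silently dropped.

Within a gene, the accepted site with the smallest |distance to stop| is
proximal (ties toward the upstream, i.e. negative-distance, site); all
others are distal. `distal_ratio` is distal reads over all site-assigned
reads per sample, null when a sample has none.

## Shift test

The two-sided Fisher's exact p-value is computed by enumerating the
hypergeometric distribution over the observed margins in exact integer
arithmetic (`math.comb`), summing the probabilities not exceeding the
observed one with the conventional 1 + 1e-7 relative slack, and converting
to float once at the end; tests require agreement with an independent
enumeration (and with `scipy.stats.fisher_exact`) to 1e-12 on all tables
with margins ≤ 30. The odds ratio is ad/bc, with a 0.5 continuity
correction applied (and flagged in the result) only when a cell is zero.
The test operates on read-level distance vectors; callers who prefer a
gene-level unit can pass one distance per site instead.

## Simulator

`simulate_library` emulates the features of real libraries the pipeline
must survive: cleavage jitter (rounded normal, default sd 1.5 nt, clamped
to the terminal exon), tail-length dispersion (truncated normal, default
mean 60 / sd 15 nt, matching reported median tails of ~60 nt in mammalian
cell lines), non-A substitutions in tails (default 2%), PCR duplicates
(default 30%, identical insert + UMI, independent index errors and
orientation), per-base index errors (default 1%), and random read
orientation. Defaults — 50 genes, two sites at +20/+220 nt from the stop
codon, usage 0.7/0.3, 60 reads/gene pooled over two samples — are the
reference study conditions used throughout the tests and the acceptance
script. The default sample indices (`AACCGGTT`, `GGTTAACC`) are Hamming
distance 8 apart, so single index errors are corrected and misassignment
requires ≥ 7 errors in one index.

What it does **not** model: sequencer-specific error profiles and quality
scores (bases are emitted error-free outside the modelled noise sources),
expression-level variation between genes, internal priming artifacts,
chimeric molecules, and overlapping gene loci. Passing tests therefore
demonstrate correctness of the algorithms under realistic read structure
and noise, not robustness to every artifact of real sequencing runs;
alignment itself is likewise out of scope (truth alignments or any spliced
aligner's SAM/PAF are accepted).

One master seed drives everything; each read uses a substream keyed
(seed, stream, read counter), so identical seeds give byte-identical
FASTQ/SAM output and read subsets are individually reproducible.

## Problem sizes and numerical notes

The test suite and acceptance script run at desk scale by design: 1000
random greedy instances of ≤ 60 read ends; a 50-gene / ~3900-read
end-to-end library; 6 spike-ins × 50 reads; Fisher enumeration over all
~164k tables with margins ≤ 30; 100 + 100 shift-test replicates at 500
reads per condition. Everything completes in well under a minute per
component on one CPU. Exact integer arithmetic makes the Fisher p-values
deterministic to the last bit; all other thresholds are integer
comparisons, so there are no tolerance knobs inside the pipeline itself.

## Known limitations

* Genomic (unspliced) stop-codon distances misstate the transcript distance
  for the rare poly(A) site upstream of the terminal exon's start.
* The suffix tail heuristic over-extends on A-rich 3' transcript ends; it is
  a fallback, not the primary caller.
* Multi-gene read discarding is conservative: overlapping genes on the same
  strand lose their shared 3' ends entirely.
* UMI collapsing is per sample, not per gene; two distinct molecules
  sharing a 12-mer UMI within a sample (birthday-rare at typical depths)
  collapse to one.
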