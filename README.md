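# bowlseq

Poly(A) tail length and alternative-polyadenylation (APA) profiling from
structured long reads.

## What problem this solves

Cleavage/polyadenylation of an mRNA can occur at several positions
downstream of the stop codon. Which site is used — *proximal* (near the stop
codon, short 3' UTR) or *distal* (far from it, long 3' UTR) — changes
transcript stability, and shifts in proximal/distal usage between
conditions are a regulatory phenotype. High-accuracy long reads (e.g.
PacBio CCS) can read through the homopolymeric poly(A) tail, so a single
read yields the exact cleavage position *and* the exact tail sequence.

`bowlseq` processes libraries whose molecules have the layout

```
TSO — transcript — poly(A) tail — anchor — UMI(12 nt) — sample index(8 bp)
```

and provides, for people analysing such data:

* structured-read parsing (orientation, trimming, rejection accounting),
  Hamming-tolerant demultiplexing (1 mismatch), and per-sample UMI
  deduplication;
* per-read poly(A) tail length and non-A composition (from the 3' soft clip
  of a spliced alignment, or alignment-free for barcoded spike-ins);
* read 3'-end extraction from SAM/PAF, strand-matched gene assignment with
  a downstream flank, multi-gene reads discarded;
* greedy poly(A)-site calling and a proximal/distal shift test;
* a seeded simulator that generates whole libraries with ground truth, so
  every stage can be validated end to end.

## The method at its core

**Site calling.** For one gene, pooled over samples, every distinct read-end
position *c* is a candidate with windowed depth
`d(c) = #{reads : |pos − c| ≤ 2}` (5-nt centered window). Greedily: take the
deepest remaining candidate (ties → smallest coordinate); accept it if
`d ≥ 2` and it lies more than 15 nt from every accepted site; remove it;
stop when no candidate reaches depth 2. Reads are counted at their nearest
accepted site when within 10 bp of it.

**Shift statistic.** Within each gene the accepted site nearest the stop
codon is proximal, the rest distal. Between two conditions A and B, reads
are classified by |distance to stop codon| ≤ 50 bp vs > 50 bp and the 2×2
table is tested with a two-sided Fisher's exact test, computed by exact
integer hypergeometric enumeration:

```
p = Σ_{k : P(k) ≤ P(a)(1+1e-7)} C(r1,k) C(r2,c1−k) / C(n,c1)
```

## Worked example

Simulate a small two-condition library (6 genes, two poly(A) sites per gene
at +20/+220 nt from the stop codon, 70/30 usage, 30% PCR duplicates, 1%
index errors) and run the full pipeline on it:

```bash
bowlseq simulate --seed 5 --outdir sim --n-genes 6 --reads-per-gene 30
bowlseq run --fastq sim/reads.fastq --sample-sheet sim/sample_sheet.tsv \
    --annotation sim/annotation.refgene.tsv \
    --alignments sim/truth_alignments.sam --outdir out
```

The run prints its stage counts (excerpt):

```
"demultiplexed": { "condA": 125, "condB": 114 },
"deduplicated":  { "condA": 95,  "condB": 85 },
"ends_with_tail": 180,
"gene_assignment": { "assigned": 180 }
```

239 raw reads (180 unique molecules + duplicates) are demultiplexed with
zero losses; UMI collapsing removes exactly the simulated duplicates; all
180 read ends land in their source gene. `out/sites.tsv` then holds two
sites per gene with per-sample counts, and the shift test compares the
conditions:

```bash
bowlseq shift --reads-at-sites out/reads_at_sites.tsv \
    --condition-a condA --condition-b condB
{"table": [[66, 29], [50, 35]], "odds_ratio": 1.593, "p_value": 0.161, ...}
```

Here 66/95 condA reads and 50/85 condB reads are proximal (within 50 bp of
the stop codon); with both conditions simulated at identical usage the test
is, correctly, far from significant. `out/manifest.json` records every
parameter and count for the run.

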