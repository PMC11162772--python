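"""Synthetic library generator with complete ground truth.

Emits CCS-like structured reads (TSO + spliced transcript + poly(A) tail +
anchor + UMI + sample index) from configurable gene models with one or more
poly(A) sites at chosen usage probabilities, plus barcoded spike-in
constructs with defined tail lengths. The generator emulates the stochastic
features the pipeline must be robust to — cleavage jitter around the true
site, non-A substitutions in tails, PCR duplicates sharing a UMI, per-base
index sequencing errors, and random read orientation — and records every
choice in a truth table.

Randomness flows through one master seed; each read draws from its own
counter-derived substream, so output is bitwise reproducible and any subset
of reads is reproducible independently of the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneModel
from .readprep import DEFAULT_ANCHOR, DEFAULT_TSO, CcsRead, reverse_complement
from .tailcall import SpikeIn

__all__ = [
    "TailDistribution",
    "GeneSimSpec",
    "SimConfig",
    "SimulatedLibrary",
    "random_reference",
    "make_gene_specs",
    "default_spikeins",
    "simulate_library",
    "simulate_truth_alignments",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_SAMPLES: tuple[tuple[str, str], ...] = (
    ("condA", "AACCGGTT"),
    ("condB", "GGTTAACC"),
)


@dataclass(frozen=True)
class TailDistribution:
    """Tail-length model: a constant length or a truncated normal.

    ``normal`` draws round(N(mean, sd)) clipped at 0; ``constant`` always
    returns round(mean). Defaults follow the ~60-nt median poly(A) tails
    reported for mammalian cell lines.
    """

    kind: str = "normal"
    mean: float = 60.0
    sd: float = 15.0

    def draw(self, rng: np.random.Generator) -> int:
        if self.kind == "constant":
            return max(0, int(round(self.mean)))
        if self.kind == "normal":
            return max(0, int(round(rng.normal(self.mean, self.sd))))
        raise ValueError(f"unknown tail distribution kind {self.kind!r}")


@dataclass(frozen=True)
class GeneSimSpec:
    """A gene plus its true poly(A) sites and usage probabilities.

    ``site_offsets`` are nt downstream of the stop codon in transcription
    direction; ``usage`` must sum to 1 and match in length.
    """

    model: GeneModel
    site_offsets: tuple[int, ...] = (20, 220)
    usage: tuple[float, ...] = (0.7, 0.3)
    tail: TailDistribution = field(default_factory=TailDistribution)

    def __post_init__(self) -> None:
        if len(self.site_offsets) != len(self.usage):
            raise ValueError("site_offsets and usage must have equal length")
        if abs(sum(self.usage) - 1.0) > 1e-9:
            raise ValueError("usage probabilities must sum to 1")

    def site_positions(self) -> list[int]:
        stop = self.model.stop_codon_pos
        sign = 1 if self.model.strand == "+" else -1
        return [stop + sign * off for off in self.site_offsets]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated run (defaults = the reference setup).

    Defaults: two-sample library, 60 reads per gene pooled over samples,
    cleavage jitter sd 1.5 nt, 30% PCR-duplicate rate, 1% per-base index
    error, 2% non-A substitution rate inside tails.
    """

    seed: int = 0
    genes: tuple[GeneSimSpec, ...] = ()
    spikeins: tuple[SpikeIn, ...] = ()
    samples: tuple[tuple[str, str], ...] = DEFAULT_SAMPLES
    reads_per_gene: int = 60
    spike_reads: int = 50
    non_a_rate: float = 0.02
    duplicate_rate: float = 0.3
    index_error_rate: float = 0.01
    cleavage_jitter_sd: float = 1.5

    def __post_init__(self) -> None:
        for name in ("non_a_rate", "duplicate_rate", "index_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cleavage_jitter_sd < 0:
            raise ValueError("cleavage_jitter_sd must be >= 0")

    @property
    def sample_sheet(self) -> dict[str, str]:
        return {index: name for name, index in self.samples}


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-base substitution to a uniformly chosen *different* base."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _tail_seq(rng: np.random.Generator, length: int, non_a_rate: float) -> str:
    return _mutate(rng, "A" * length, non_a_rate)


def random_reference(
    seed: int = 0, n_chrom: int = 2, length: int = 80_000
) -> dict[str, str]:
    """A small random genome for simulation and tests."""
    rng = np.random.default_rng([seed, 101])
    return {f"chr{i + 1}": _random_dna(rng, length) for i in range(n_chrom)}


def make_gene_specs(
    reference: Mapping[str, str],
    n_genes: int = 50,
    site_offsets: tuple[int, ...] = (20, 220),
    usage: tuple[float, ...] = (0.7, 0.3),
    tail: TailDistribution | None = None,
    gene_length: int = 1200,
    spacing: int = 3000,
    n_exons: int = 1,
) -> list[GeneSimSpec]:
    """Lay out non-overlapping genes across the reference.

    Genes alternate chromosomes and strands; the stop codon is placed so all
    poly(A) sites (plus jitter) stay inside the terminal exon. ``n_exons``
    may be 1 or 2 (a 150-nt intron splits the gene near its 5' end).
    """
    tail = tail or TailDistribution()
    chroms = list(reference)
    specs: list[GeneSimSpec] = []
    max_off = max(site_offsets)
    for i in range(n_genes):
        chrom = chroms[i % len(chroms)]
        slot = i // len(chroms)
        start = 1000 + slot * spacing
        end = start + gene_length
        if end + 100 > len(reference[chrom]):
            raise ValueError("reference too short for requested gene layout")
        strand = "+" if i % 2 == 0 else "-"
        if n_exons == 1:
            exons = [(start, end)]
        elif n_exons == 2:
            exons = [(start, start + 200), (start + 350, end)]
        else:
            raise ValueError("n_exons must be 1 or 2")
        if strand == "+":
            stop = end - max_off - 180
        else:
            stop = start + max_off + 180
            if n_exons == 2 and stop < start + 350:
                raise ValueError("gene too short for sites on - strand")
        specs.append(
            GeneSimSpec(
                model=GeneModel.from_exons(f"gene{i:03d}", chrom, strand, exons, stop),
                site_offsets=tuple(site_offsets),
                usage=tuple(usage),
                tail=tail,
            )
        )
    return specs


def default_spikeins(
    tail_lengths: Sequence[int] = (10, 30, 50, 80, 120, 200),
    body_length: int = 300,
    seed: int = 0,
) -> list[SpikeIn]:
    """Barcoded constructs with defined tail lengths (one per length)."""
    rng = np.random.default_rng([seed, 202])
    body = _random_dna(rng, body_length)
    barcodes = ["AATTCCGG", "CCAAGGTT", "GGTTAACC"[::-1], "TTGGCCAA",
                "ACACGTGT", "CAGTCAGT"]
    if len(tail_lengths) > len(barcodes):
        raise ValueError("at most 6 default spike-ins")
    return [
        SpikeIn(f"spike_{L:03d}", barcodes[i], body, int(L))
        for i, L in enumerate(tail_lengths)
    ]


def transcript_seq(reference: Mapping[str, str], gene: GeneModel, cleavage: int) -> str:
    """Spliced transcript sequence, 5' to 3', ending at ``cleavage``."""
    ref = reference[gene.chrom]
    if gene.strand == "+":
        parts = [
            ref[e.start : min(e.end, cleavage + 1)]
            for e in gene.exons
            if e.start <= cleavage
        ]
        return "".join(parts)
    parts = [
        ref[max(e.start, cleavage) : e.end] for e in gene.exons if e.end > cleavage
    ]
    return reverse_complement("".join(parts))


def _terminal_exon_bounds(gene: GeneModel, site: int) -> tuple[int, int]:
    for e in gene.exons:
        if e.start <= site < e.end:
            return e.start, e.end - 1
    raise ValueError(
        f"poly(A) site {site} outside every exon of gene {gene.gene_id}"
    )


@dataclass
class SimulatedLibrary:
    """The output bundle: reads, ground truth, and all reference inputs."""

    config: SimConfig
    reference: dict[str, str]
    reads: list[CcsRead]
    truth: pd.DataFrame
    inserts: dict[str, str]

    @property
    def genes(self) -> list[GeneModel]:
        return [gs.model for gs in self.config.genes]

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")

    def write_reference(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.reference.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_annotation(self, path: str | Path) -> None:
        """refGene-style table (name..exonEnds columns) for the gene models."""
        with open(path, "w") as fh:
            for g in self.genes:
                start, end = g.span
                if g.strand == "+":
                    cds_start, cds_end = start, g.stop_codon_pos + 1
                else:
                    cds_start, cds_end = g.stop_codon_pos, end
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            g.gene_id,
                            g.chrom,
                            g.strand,
                            start,
                            end,
                            cds_start,
                            cds_end,
                            len(g.exons),
                            ",".join(str(e.start) for e in g.exons) + ",",
                            ",".join(str(e.end) for e in g.exons) + ",",
                        )
                    )
                    + "\n"
                )

    def write_sample_sheet(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tindex\n")
            for name, index in self.config.samples:
                fh.write(f"{name}\t{index}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def simulate_library(
    config: SimConfig, reference: Mapping[str, str] | None = None
) -> SimulatedLibrary:
    """Generate a structured-read library plus its truth table.

    Every read is TSO + transcript + tail + anchor + UMI + index; roughly
    half are emitted reverse-complemented. With probability
    ``duplicate_rate`` a read is re-emitted as a PCR duplicate: identical
    insert and UMI, independent index errors and orientation.
    """
    reference = dict(reference) if reference is not None else random_reference(config.seed)
    for gs in config.genes:
        if gs.model.chrom not in reference:
            raise ValueError(f"gene {gs.model.gene_id}: chromosome not in reference")
        _, end = gs.model.span
        if end > len(reference[gs.model.chrom]):
            raise ValueError(f"gene {gs.model.gene_id}: span outside reference")

    sample_names = [name for name, _ in config.samples]
    sample_index = dict(config.samples)
    reads: list[CcsRead] = []
    rows: list[dict] = []
    inserts: dict[str, str] = {}

    def emit(rng, read_id, sample, source, kind, site_pos, cleavage, insert, tail_len,
             umi, is_dup, parent):
        observed_index = _mutate(rng, sample_index[sample], config.index_error_rate)
        seq = DEFAULT_TSO + insert + DEFAULT_ANCHOR + umi + observed_index
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(CcsRead(read_id, seq))
        inserts[read_id] = insert
        rows.append(
            {
                "read_id": read_id,
                "sample": sample,
                "source_id": source,
                "kind": kind,
                "true_site_pos": site_pos,
                "cleavage_pos": cleavage,
                "true_tail_len": tail_len,
                "true_umi": umi,
                "is_duplicate": is_dup,
                "parent_id": parent,
            }
        )

    counter = 0
    for gs in config.genes:
        sites = gs.site_positions()
        for _ in range(config.reads_per_gene):
            rng = np.random.default_rng([config.seed, 1, counter])
            read_id = f"r{counter:07d}"
            sample = sample_names[int(rng.integers(len(sample_names)))]
            k = int(rng.choice(len(sites), p=np.asarray(gs.usage)))
            site = sites[k]
            lo, hi = _terminal_exon_bounds(gs.model, site)
            jitter = (
                int(round(rng.normal(0.0, config.cleavage_jitter_sd)))
                if config.cleavage_jitter_sd > 0
                else 0
            )
            cleavage = int(np.clip(site + jitter, lo, hi))
            tail_len = gs.tail.draw(rng)
            tail = _tail_seq(rng, tail_len, config.non_a_rate)
            insert = transcript_seq(reference, gs.model, cleavage) + tail
            umi = _random_dna(rng, 12)
            emit(rng, read_id, sample, gs.model.gene_id, "gene", site, cleavage,
                 insert, tail_len, umi, False, "")
            if rng.random() < config.duplicate_rate:
                emit(rng, f"{read_id}.dup", sample, gs.model.gene_id, "gene", site,
                     cleavage, insert, tail_len, umi, True, read_id)
            counter += 1

    for sp in config.spikeins:
        for _ in range(config.spike_reads):
            rng = np.random.default_rng([config.seed, 2, counter])
            read_id = f"s{counter:07d}"
            sample = sample_names[int(rng.integers(len(sample_names)))]
            tail = _tail_seq(rng, sp.true_tail_len, config.non_a_rate)
            insert = sp.reference_seq + tail + sp.barcode
            umi = _random_dna(rng, 12)
            emit(rng, read_id, sample, sp.name, "spikein", -1, -1, insert,
                 sp.true_tail_len, umi, False, "")
            if rng.random() < config.duplicate_rate:
                emit(rng, f"{read_id}.dup", sample, sp.name, "spikein", -1, -1,
                     insert, sp.true_tail_len, umi, True, read_id)
            counter += 1

    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id", "sample", "source_id", "kind", "true_site_pos",
            "cleavage_pos", "true_tail_len", "true_umi", "is_duplicate",
            "parent_id",
        ],
    )
    return SimulatedLibrary(config, reference, reads, truth, inserts)


def _alignment_blocks(gene: GeneModel, cleavage: int) -> list[tuple[int, int]]:
    """Reference blocks covered by the transcript (5' end .. cleavage)."""
    if gene.strand == "+":
        return [
            (e.start, min(e.end, cleavage + 1))
            for e in gene.exons
            if e.start <= cleavage
        ]
    return [(max(e.start, cleavage), e.end) for e in gene.exons if e.end > cleavage]


def simulate_truth_alignments(library: SimulatedLibrary, path: str | Path) -> int:
    """Write perfect SAM alignments of each clean insert (tail soft-clipped).

    Every gene-derived read (duplicates included) gets one primary record:
    the transcript part matches its exon blocks exactly (``N`` across
    introns) and the tail is a 3' soft clip. On the minus strand the stored
    sequence is the reverse complement and the soft clip leads the CIGAR, as
    SAM requires. Spike-in reads have no genomic origin and are skipped.
    Returns the number of records written.
    """
    ref_names = list(library.reference)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": name, "LN": len(seq)} for name, seq in library.reference.items()
        ],
    }
    gene_by_id = {g.gene_id: g for g in library.genes}
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in library.truth.itertuples(index=False):
            if row.kind != "gene":
                continue
            gene = gene_by_id[row.source_id]
            insert = library.inserts[row.read_id]
            tail_len = int(row.true_tail_len)
            blocks = _alignment_blocks(gene, int(row.cleavage_pos))
            cigar = []
            for i, (s, e) in enumerate(blocks):
                if i:
                    cigar.append(f"{s - blocks[i - 1][1]}N")
                cigar.append(f"{e - s}M")
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = row.read_id
            rec.reference_id = ref_names.index(gene.chrom)
            rec.reference_start = blocks[0][0]
            rec.mapping_quality = 60
            if gene.strand == "+":
                rec.flag = 0
                rec.query_sequence = insert
                rec.cigarstring = "".join(cigar) + (f"{tail_len}S" if tail_len else "")
            else:
                rec.flag = 16
                rec.query_sequence = reverse_complement(insert)
                rec.cigarstring = (f"{tail_len}S" if tail_len else "") + "".join(cigar)
            out.write(rec)
            n += 1
    return n
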