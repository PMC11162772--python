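"""Gene models for 3'-end analysis: exon merging and stop-codon distances.

Alternative polyadenylation (APA) is quantified relative to the stop codon of
each gene: a cleavage site just downstream of the stop codon produces a short
3' UTR ("proximal" APA), a site far downstream a long one ("distal" APA).
This module loads gene annotations (UCSC refGene-style tables or BED12),
collapses each gene's transcripts into a single model with merged,
non-redundant exons, and provides the strand-aware genomic distance from any
site to the stop codon.

Coordinates are 0-based half-open throughout, as in BED. ``stop_codon_pos``
is the 0-based genomic coordinate of the *last* base of the stop codon in
transcription direction, so a site at the stop codon has distance 0 and
positive distances point into the 3' UTR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "merge_intervals",
    "load_annotation",
    "write_bed12",
    "distance_to_stop",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of integer intervals: overlapping *and* abutting intervals merge.

    Duplicated intervals collapse trivially. Returns intervals sorted by
    start; the result is idempotent under re-merging.
    """
    ivs = sorted(set((int(s), int(e)) for s, e in intervals))
    if not ivs:
        return []
    merged = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = merged[-1]
        if s <= le:  # overlap or abut
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GeneModel:
    """One gene: merged exons plus the stop-codon coordinate.

    ``exons`` are sorted, non-overlapping, non-abutting `GenomicInterval`s on
    one chromosome and strand. Use :meth:`from_exons` to build from raw
    (possibly redundant) exon coordinates.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    stop_codon_pos: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: empty exon list")
        span_s, span_e = self.span
        if not (span_s <= self.stop_codon_pos < span_e):
            raise ValueError(
                f"gene {self.gene_id}: stop codon {self.stop_codon_pos} outside "
                f"span [{span_s}, {span_e})"
            )

    @classmethod
    def from_exons(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        exons: Iterable[tuple[int, int]],
        stop_codon_pos: int,
    ) -> "GeneModel":
        merged = [
            GenomicInterval(chrom, s, e, strand) for s, e in merge_intervals(exons)
        ]
        return cls(gene_id, chrom, strand, merged, stop_codon_pos)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    @property
    def tx_end(self) -> int:
        """Genomic coordinate of the last transcribed base (3' end)."""
        return self.span[1] - 1 if self.strand == "+" else self.span[0]


def distance_to_stop(gene: GeneModel, site_pos: int, chrom: str | None = None) -> int:
    """Signed genomic distance from the stop codon to ``site_pos``.

    Positive values are downstream of the stop codon in transcription
    direction (i.e. into the 3' UTR), negative values upstream.
    """
    if chrom is not None and chrom != gene.chrom:
        raise ValueError(
            f"site on {chrom} but gene {gene.gene_id} on {gene.chrom}"
        )
    if gene.strand == "+":
        return site_pos - gene.stop_codon_pos
    return gene.stop_codon_pos - site_pos


# ---------------------------------------------------------------------------
# Annotation I/O


def _parse_int_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x]


def load_annotation(path: str | Path, format: str = "refgene_table") -> list[GeneModel]:
    """Load gene models, merging exons per gene_id.

    Parameters
    ----------
    path
        Annotation file.
    format
        ``"refgene_table"`` — tab-separated UCSC column order
        (name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd, exonCount,
        exonStarts, exonEnds, ...); or ``"bed12"``.

    Malformed rows and noncoding rows (no CDS) are skipped with a logged
    warning. Two rows sharing a gene_id with conflicting strand raise
    ``ValueError``. When a gene has several coding transcripts the stop codon
    of the transcript with the most downstream CDS end (in transcription
    direction) is used.
    """
    if format == "refgene_table":
        rows = _read_refgene(path)
    elif format == "bed12":
        rows = _read_bed12(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    genes: dict[str, dict] = {}
    for gene_id, chrom, strand, exons, stop in rows:
        rec = genes.get(gene_id)
        if rec is None:
            genes[gene_id] = {
                "chrom": chrom,
                "strand": strand,
                "exons": list(exons),
                "stop": stop,
            }
            continue
        if rec["strand"] != strand or rec["chrom"] != chrom:
            raise ValueError(
                f"gene {gene_id}: conflicting strand/chromosome across rows"
            )
        rec["exons"].extend(exons)
        # keep the most downstream stop codon in transcription direction
        if (strand == "+" and stop > rec["stop"]) or (
            strand == "-" and stop < rec["stop"]
        ):
            rec["stop"] = stop

    return [
        GeneModel.from_exons(gid, r["chrom"], r["strand"], r["exons"], r["stop"])
        for gid, r in genes.items()
    ]


def _read_refgene(path: str | Path):
    skipped = 0
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                name, chrom, strand = fields[0], fields[1], fields[2]
                cds_start, cds_end = int(fields[5]), int(fields[6])
                starts = _parse_int_list(fields[8])
                ends = _parse_int_list(fields[9])
                if strand not in ("+", "-") or len(starts) != len(ends) or not starts:
                    raise ValueError("bad row")
                exons = list(zip(starts, ends))
            except (IndexError, ValueError):
                logger.warning("%s line %d: malformed row skipped", path, lineno)
                skipped += 1
                continue
            if cds_start >= cds_end:
                logger.warning("%s line %d: noncoding row %s skipped", path, lineno, name)
                skipped += 1
                continue
            stop = cds_end - 1 if strand == "+" else cds_start
            out.append((name, chrom, strand, exons, stop))
    if skipped:
        logger.warning("%s: %d rows skipped", path, skipped)
    return out


def _read_bed12(path: str | Path):
    skipped = 0
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chrom, start, name = f[0], int(f[1]), f[3]
                strand = f[5]
                thick_start, thick_end = int(f[6]), int(f[7])
                sizes = _parse_int_list(f[10])
                offs = _parse_int_list(f[11])
                if strand not in ("+", "-") or len(sizes) != len(offs) or not sizes:
                    raise ValueError("bad row")
                exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            except (IndexError, ValueError):
                logger.warning("%s line %d: malformed row skipped", path, lineno)
                skipped += 1
                continue
            if thick_start >= thick_end:
                logger.warning("%s line %d: noncoding row %s skipped", path, lineno, name)
                skipped += 1
                continue
            stop = thick_end - 1 if strand == "+" else thick_start
            out.append((name, chrom, strand, exons, stop))
    if skipped:
        logger.warning("%s: %d rows skipped", path, skipped)
    return out


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (thick range encodes the stop codon)."""
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.span
            if g.strand == "+":
                thick_start, thick_end = start, g.stop_codon_pos + 1
            else:
                thick_start, thick_end = g.stop_codon_pos, end
            sizes = ",".join(str(e.length) for e in g.exons)
            offs = ",".join(str(e.start - start) for e in g.exons)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom,
                        start,
                        end,
                        g.gene_id,
                        0,
                        g.strand,
                        thick_start,
                        thick_end,
                        "0,0,0",
                        len(g.exons),
                        sizes,
                        offs,
                    )
                )
                + "\n"
            )
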