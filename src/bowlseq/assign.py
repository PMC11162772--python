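"""Read-end extraction from alignments and gene assignment.

The cleavage/polyadenylation position of a read is the genomic coordinate of
its 3'-terminal aligned base: the rightmost reference base for a forward
alignment, the leftmost for a reverse one. Because clean reads carry their
(unaligned) poly(A) tail, the 3' soft clip of each primary alignment gives
the tail length directly; reads without a tail are excluded, as only
polyadenylated molecules inform 3'-end analysis.

Gene assignment places each read end inside a gene span, extended downstream
by a configurable flank so that distal poly(A) sites past the annotated gene
end are still captured. Reads overlapping more than one gene are discarded;
assignment is strand-matched, since the library is strand-resolved by
construction (TSO at the 5' end).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .annotation import GeneModel
from .readprep import parse_clean_header

logger = logging.getLogger(__name__)

__all__ = ["ReadEnd", "extract_read_ends", "assign_genes", "write_read_ends_bed"]


@dataclass
class ReadEnd:
    """The 3'-end landing position of one aligned read."""

    read_id: str
    chrom: str
    strand: str
    cleavage_pos: int
    tail_len: int
    sample: str | None = None
    gene_id: str | None = None
    #: insert coordinate where the 3' soft clip starts (original orientation)
    align_end_offset: int | None = None
    dist_to_stop: int | None = None


def _clip3(cigartuples, is_reverse: bool) -> int:
    """Length of the soft clip at the read's 3' end (original orientation)."""
    if not cigartuples:
        return 0
    op, n = cigartuples[0] if is_reverse else cigartuples[-1]
    return n if op == 4 else 0  # BAM_CSOFT_CLIP


def extract_read_ends(
    alignments: str | Path | Iterable,
    min_tail_len: int = 1,
    samples: Mapping[str, str] | None = None,
) -> tuple[list[ReadEnd], Counter]:
    """Derive read ends from primary alignments (SAM/BAM path or PAF path).

    Secondary and supplementary records are ignored; unmapped reads and reads
    whose 3' soft clip (the poly(A) tail of a clean read) is shorter than
    ``min_tail_len`` are excluded and counted. The sample is taken from a
    ``read_id|sample|UMI`` query name when present, else from ``samples``.

    Returns (read ends, counts) with counts keyed ``used``, ``unmapped``,
    ``secondary``, ``no_tail``.
    """
    if isinstance(alignments, (str, Path)) and str(alignments).endswith(".paf"):
        return _ends_from_paf(Path(alignments), min_tail_len, samples)
    if isinstance(alignments, (str, Path)):
        afile = pysam.AlignmentFile(str(alignments), check_sq=False)
        records = afile
    else:
        records = alignments
    counts: Counter = Counter()
    ends: list[ReadEnd] = []
    for rec in records:
        if rec.is_unmapped:
            counts["unmapped"] += 1
            continue
        if rec.is_secondary or rec.is_supplementary:
            counts["secondary"] += 1
            continue
        tail = _clip3(rec.cigartuples, rec.is_reverse)
        if tail < min_tail_len:
            counts["no_tail"] += 1
            continue
        base_id, sample, _ = parse_clean_header(rec.query_name)
        if sample is None and samples is not None:
            sample = samples.get(base_id)
        strand = "-" if rec.is_reverse else "+"
        cleavage = rec.reference_end - 1 if strand == "+" else rec.reference_start
        ends.append(
            ReadEnd(
                read_id=base_id,
                chrom=rec.reference_name,
                strand=strand,
                cleavage_pos=cleavage,
                tail_len=tail,
                sample=sample,
                align_end_offset=rec.query_length - tail,
            )
        )
        counts["used"] += 1
    return ends, counts


def _ends_from_paf(path: Path, min_tail_len: int, samples):
    counts: Counter = Counter()
    ends: list[ReadEnd] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            tags = dict(
                (t.split(":", 2)[0], t.split(":", 2)[2]) for t in f[12:] if ":" in t
            )
            if tags.get("tp", "P") != "P":
                counts["secondary"] += 1
                continue
            qlen, qend = int(f[1]), int(f[3])
            strand, tstart, tend = f[4], int(f[7]), int(f[8])
            # PAF query coordinates are in the original read orientation
            tail = qlen - qend
            if tail < min_tail_len:
                counts["no_tail"] += 1
                continue
            base_id, sample, _ = parse_clean_header(f[0])
            if sample is None and samples is not None:
                sample = samples.get(base_id)
            cleavage = tend - 1 if strand == "+" else tstart
            ends.append(
                ReadEnd(
                    read_id=base_id,
                    chrom=f[5],
                    strand=strand,
                    cleavage_pos=cleavage,
                    tail_len=tail,
                    sample=sample,
                    align_end_offset=qend,
                )
            )
            counts["used"] += 1
    return ends, counts


def assign_genes(
    ends: Iterable[ReadEnd], genes: Sequence[GeneModel], flank: int = 1000
) -> tuple[list[ReadEnd], Counter]:
    """Assign read ends to genes; discard ends overlapping several genes.

    A read end matches a gene when its cleavage position lies within the gene
    span extended 3'-ward by ``flank`` nt, on the same chromosome and strand.
    Returns (assigned ends with gene_id set, counts keyed ``assigned``,
    ``multi_gene``, ``unassigned``). Assignment is independent of both read
    and gene input order.
    """
    by_loc: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for g in genes:
        start, end = g.span
        if g.strand == "+":
            end += flank
        else:
            start = max(0, start - flank)
        by_loc.setdefault((g.chrom, g.strand), []).append((start, end, g.gene_id))
    for spans in by_loc.values():
        spans.sort()

    counts: Counter = Counter()
    assigned: list[ReadEnd] = []
    for e in ends:
        hits = [
            gid
            for s, t, gid in by_loc.get((e.chrom, e.strand), [])
            if s <= e.cleavage_pos < t
        ]
        if len(hits) == 1:
            assigned.append(replace(e, gene_id=hits[0]))
            counts["assigned"] += 1
        elif hits:
            counts["multi_gene"] += 1
        else:
            counts["unassigned"] += 1
    return assigned, counts


def write_read_ends_bed(ends: Iterable[ReadEnd], path: str | Path) -> None:
    """BED6 of read ends: name=read_id, score=tail_len."""
    with open(path, "w") as fh:
        for e in ends:
            fh.write(
                f"{e.chrom}\t{e.cleavage_pos}\t{e.cleavage_pos + 1}\t"
                f"{e.read_id}\t{e.tail_len}\t{e.strand}\n"
            )
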