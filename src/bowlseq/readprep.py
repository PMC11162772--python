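"""Structured-read parsing: orient, trim, demultiplex and deduplicate CCS reads.

A Bowl-seq library molecule reads, 5' to 3' of the mRNA sense strand::

    TSO -- transcript -- poly(A) tail -- anchor -- UMI(12) -- index(8)

The TSO (template-switch oligo) marks the cDNA 5' end; the constant anchor
segment of the binding oligo sits between the poly(A) tail and the 12-nt UMI;
the 8-bp sample index follows the UMI at the read 3' end. CCS reads arrive in
either orientation, so parsing searches both the read and its reverse
complement. A read is kept only when the TSO is found on one end and the
anchor on the other; everything between TSO and anchor is the insert
(transcript + tail).

Demultiplexing assigns each read to the unique sample whose index is within a
Hamming-distance tolerance of the observed index (default 1 mismatch, the
``-m 1`` convention of the Demultiplex tool). UMI deduplication collapses
reads sharing a 12-mer within each sample, keeping the longest insert.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "OligoLayout",
    "CcsRead",
    "CleanRead",
    "ReadRejected",
    "orient_and_trim",
    "prep_reads",
    "demultiplex",
    "validate_sample_sheet",
    "dedup_umi",
    "reverse_complement",
    "hamming",
    "read_fastx",
    "read_sample_sheet",
    "write_clean_fastq",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: TSO as sequenced: AAGCAGTGGTATCAACGCAGAGTACAT + rGrGrG read as GGG.
DEFAULT_TSO = "AAGCAGTGGTATCAACGCAGAGTACATGGG"
#: Constant binding-oligo segment immediately 5' of the UMI.
DEFAULT_ANCHOR = "CGGAAGCAGTGGTATCAACGCAGAGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class OligoLayout:
    """Expected segment layout of a structured read."""

    tso_seq: str = DEFAULT_TSO
    anchor_seq: str = DEFAULT_ANCHOR
    index_len: int = 8
    umi_len: int = 12
    max_index_mismatch: int = 1
    #: mismatches tolerated when locating TSO/anchor (no indels)
    max_probe_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.index_len <= 0 or self.umi_len <= 0:
            raise ValueError("index_len and umi_len must be positive")
        if self.max_index_mismatch < 0 or self.max_probe_mismatch < 0:
            raise ValueError("mismatch tolerances must be >= 0")


@dataclass(frozen=True)
class CcsRead:
    """A raw circular-consensus read."""

    read_id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty read sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError("quality string length mismatch")


@dataclass
class CleanRead:
    """An oriented, trimmed read: insert (transcript + tail) plus metadata."""

    read_id: str
    umi: str
    insert_seq: str
    orientation_flipped: bool
    sample: str | None = None
    raw_index: str | None = None


class ReadRejected(Exception):
    """Raised by :func:`orient_and_trim` with a machine-readable reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def _find_approx(seq: str, probe: str, max_mismatch: int) -> int:
    """Leftmost start of ``probe`` in ``seq`` with <= max_mismatch substitutions.

    Exact ``str.find`` fast path; mismatch scan is vectorized over the probe.
    Returns -1 when absent. No indels are considered — CCS reads are
    high-accuracy, so substitution-only matching suffices.
    """
    i = seq.find(probe)
    if i >= 0:
        return i
    if max_mismatch == 0 or len(seq) < len(probe):
        return -1
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(probe.encode(), dtype=np.uint8)
    n = len(a) - len(p) + 1
    mm = np.zeros(n, dtype=np.int32)
    for j in range(len(p)):
        mm += a[j : j + n] != p[j]
    hits = np.nonzero(mm <= max_mismatch)[0]
    return int(hits[0]) if hits.size else -1


def orient_and_trim(read: CcsRead, layout: OligoLayout | None = None) -> CleanRead:
    """Parse one CCS read into a :class:`CleanRead`, or raise :class:`ReadRejected`.

    Rejection reasons: ``"no_tso"`` (TSO absent in both orientations),
    ``"chimera"`` (TSO found in both orientations, i.e. on both ends),
    ``"no_anchor"`` (anchor absent downstream of the TSO), ``"truncated"``
    (too few bases after the anchor for UMI + index).
    """
    layout = layout or OligoLayout()
    tol = layout.max_probe_mismatch
    fwd = _find_approx(read.seq, layout.tso_seq, tol)
    rc_seq = reverse_complement(read.seq)
    rev = _find_approx(rc_seq, layout.tso_seq, tol)
    if fwd >= 0 and rev >= 0:
        raise ReadRejected("chimera")
    if fwd < 0 and rev < 0:
        raise ReadRejected("no_tso")
    flipped = fwd < 0
    seq = rc_seq if flipped else read.seq
    tso_end = (rev if flipped else fwd) + len(layout.tso_seq)
    downstream = seq[tso_end:]
    a = _find_approx(downstream, layout.anchor_seq, tol)
    if a < 0:
        raise ReadRejected("no_anchor")
    a_end = a + len(layout.anchor_seq)
    if len(downstream) - a_end < layout.umi_len + layout.index_len:
        raise ReadRejected("truncated")
    return CleanRead(
        read_id=read.read_id,
        umi=downstream[a_end : a_end + layout.umi_len],
        insert_seq=downstream[:a],
        orientation_flipped=flipped,
        raw_index=downstream[
            a_end + layout.umi_len : a_end + layout.umi_len + layout.index_len
        ],
    )


def prep_reads(
    reads: Iterable[CcsRead], layout: OligoLayout | None = None
) -> tuple[list[CleanRead], Counter]:
    """Parse a batch of reads; returns (kept reads, per-reason rejection counts)."""
    layout = layout or OligoLayout()
    kept: list[CleanRead] = []
    rejected: Counter = Counter()
    for read in reads:
        try:
            kept.append(orient_and_trim(read, layout))
        except ReadRejected as exc:
            rejected[exc.reason] += 1
    return kept, rejected


def validate_sample_sheet(
    sample_sheet: Mapping[str, str], layout: OligoLayout
) -> None:
    """Check index lengths and pairwise separability of a sample sheet.

    Indices must all have ``layout.index_len`` bases and pairwise Hamming
    distance > 2 * max_index_mismatch, otherwise a read could sit within
    tolerance of two samples; that is a hard error.
    """
    indices = list(sample_sheet)
    for idx in indices:
        if len(idx) != layout.index_len:
            raise ValueError(
                f"index {idx!r} has length {len(idx)}, expected {layout.index_len}"
            )
    for i, a in enumerate(indices):
        for b in indices[i + 1 :]:
            if hamming(a, b) <= 2 * layout.max_index_mismatch:
                raise ValueError(
                    f"ambiguous sample sheet: indices {a!r} and {b!r} are within "
                    f"2 x max_index_mismatch = {2 * layout.max_index_mismatch}"
                )


def demultiplex(
    reads: Iterable[CleanRead],
    sample_sheet: Mapping[str, str],
    layout: OligoLayout | None = None,
) -> tuple[dict[str, list[CleanRead]], list[CleanRead]]:
    """Partition reads by sample index within Hamming tolerance.

    ``sample_sheet`` maps index sequence -> sample name. Returns
    (per-sample lists, unassigned reads); the partition is exhaustive and
    disjoint. Reads whose observed index is farther than
    ``layout.max_index_mismatch`` from every sheet index are unassigned.
    """
    layout = layout or OligoLayout()
    validate_sample_sheet(sample_sheet, layout)
    by_sample: dict[str, list[CleanRead]] = {s: [] for s in sample_sheet.values()}
    unassigned: list[CleanRead] = []
    for read in reads:
        if read.raw_index is None or len(read.raw_index) != layout.index_len:
            unassigned.append(read)
            continue
        hits = [
            sample
            for index, sample in sample_sheet.items()
            if hamming(read.raw_index, index) <= layout.max_index_mismatch
        ]
        if len(hits) == 1:
            by_sample[hits[0]].append(replace(read, sample=hits[0]))
        else:
            unassigned.append(read)
    return by_sample, unassigned


def dedup_umi(reads: Iterable[CleanRead]) -> list[CleanRead]:
    """Collapse UMI duplicates: one read per distinct (sample, UMI) pair.

    The retained read has the longest insert; ties break to the
    lexicographically smallest read_id. Output is ordered by read_id, so the
    operation is idempotent and input-order independent.
    """
    best: dict[tuple[str | None, str], CleanRead] = {}
    for read in reads:
        key = (read.sample, read.umi)
        cur = best.get(key)
        if cur is None or (-len(read.insert_seq), read.read_id) < (
            -len(cur.insert_seq),
            cur.read_id,
        ):
            best[key] = read
    return sorted(best.values(), key=lambda r: r.read_id)


# ---------------------------------------------------------------------------
# I/O helpers


def read_fastx(path: str | Path) -> list[CcsRead]:
    """Read FASTQ or FASTA (optionally gzipped), by file extension."""
    path = Path(path)
    name = path.name.lower()
    opener = gzip.open if name.endswith(".gz") else open
    stem = name[:-3] if name.endswith(".gz") else name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    reads = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            reads.append(CcsRead(rec.id, str(rec.seq), qual))
    return reads


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample, index) -> {index: sample} map."""
    sheet: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() == "sample":
                continue
            sample, index = fields[0], fields[1]
            sheet[index] = sample
    return sheet


def write_clean_fastq(reads: Iterable[CleanRead], path: str | Path) -> None:
    """Write inserts as FASTQ with ``read_id|sample|UMI`` headers."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"@{r.read_id}|{r.sample}|{r.umi}\n{r.insert_seq}\n+\n"
                f"{'I' * len(r.insert_seq)}\n"
            )


def parse_clean_header(header: str) -> tuple[str, str | None, str | None]:
    """Split a ``read_id|sample|UMI`` header; missing parts become None."""
    parts = header.split("|")
    if len(parts) >= 3:
        return parts[0], parts[1], parts[2]
    return parts[0], None, None
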