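"""Poly(A) tail calling: boundary, length, and non-A composition.

The poly(A) tail of a clean read is the 3' segment of the insert that does
not align to the genome. The primary caller therefore takes the 3' soft-clip
boundary of a spliced alignment (the insert coordinate of the first
unaligned base) and everything 3' of it is tail. An alignment-free fallback,
used for spike-ins and testing, scans insert suffixes for the longest
A-dominated run.

Tails are not pure adenosine: non-A residues occur and their usage is a
phenotype of interest, so each call carries a non-A count and fraction, and
summaries report both the per-read fraction and the fraction of reads with
at least one non-A residue.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .readprep import CleanRead, hamming

__all__ = [
    "TailCall",
    "SpikeIn",
    "call_tail_softclip",
    "call_tail_suffix",
    "gene_tail_summary",
    "spikein_calls",
    "spikein_report",
]


@dataclass(frozen=True)
class TailCall:
    read_id: str
    tail_len: int
    tail_seq: str
    non_a_count: int
    non_a_frac: float
    method: str

    def __post_init__(self) -> None:
        if self.tail_len != len(self.tail_seq):
            raise ValueError("tail_len must equal len(tail_seq)")
        if self.non_a_count > self.tail_len:
            raise ValueError("non_a_count exceeds tail length")


@dataclass(frozen=True)
class SpikeIn:
    """A synthetic construct with a known tail length and 3' barcode."""

    name: str
    barcode: str
    reference_seq: str
    true_tail_len: int

    def __post_init__(self) -> None:
        if self.true_tail_len < 0:
            raise ValueError("true_tail_len must be >= 0")


def _make_call(read_id: str, tail_seq: str, method: str) -> TailCall:
    n = len(tail_seq)
    non_a = sum(1 for b in tail_seq if b not in "Aa")
    return TailCall(read_id, n, tail_seq, non_a, non_a / n if n else 0.0, method)


def call_tail_softclip(read: CleanRead, alignment_end_offset: int) -> TailCall:
    """Tail = insert bases 3' of the alignment end.

    ``alignment_end_offset`` is the insert coordinate of the last aligned
    base + 1 (where the 3' soft clip starts). ``offset == len(insert)`` means
    the read aligned fully and has no tail.
    """
    if not 0 <= alignment_end_offset <= len(read.insert_seq):
        raise ValueError(
            f"alignment_end_offset {alignment_end_offset} outside "
            f"[0, {len(read.insert_seq)}]"
        )
    return _make_call(read.read_id, read.insert_seq[alignment_end_offset:], "softclip")


def call_tail_suffix(
    read: CleanRead | str, min_a_frac: float = 0.8, min_len: int = 5
) -> TailCall:
    """Alignment-free tail call: longest A-dominated suffix.

    The tail is the longest suffix ending at the read 3' end whose A-fraction
    is >= ``min_a_frac`` and whose first base is an A; if the best such
    suffix is shorter than ``min_len`` the tail is empty.
    """
    if not 0.5 < min_a_frac <= 1:
        raise ValueError("min_a_frac must be in (0.5, 1]")
    if isinstance(read, str):
        read_id, seq = "", read
    else:
        read_id, seq = read.read_id, read.insert_seq
    n = len(seq)
    best_start = n
    a_count = 0
    # scan suffixes from short to long, tracking the A count incrementally
    for start in range(n - 1, -1, -1):
        if seq[start] in "Aa":
            a_count += 1
        length = n - start
        if seq[start] in "Aa" and a_count >= min_a_frac * length:
            best_start = start
    if n - best_start < min_len:
        best_start = n
    return _make_call(read_id, seq[best_start:], "suffix_heuristic")


def gene_tail_summary(
    calls_by_gene: Mapping[str, Sequence[TailCall]]
) -> tuple[pd.DataFrame, float | None]:
    """Per-gene tail-length summaries plus the global median of gene medians.

    Empty gene groups are excluded. Returns a DataFrame with columns
    (gene_id, n_reads, median_tail, mean_tail, frac_reads_with_non_a) and the
    median over gene medians (None when no gene has reads).
    """
    rows = []
    for gene_id, calls in calls_by_gene.items():
        if not calls:
            continue
        lengths = [c.tail_len for c in calls]
        rows.append(
            {
                "gene_id": gene_id,
                "n_reads": len(calls),
                "median_tail": statistics.median(lengths),
                "mean_tail": statistics.fmean(lengths),
                "frac_reads_with_non_a": statistics.fmean(
                    1.0 if c.non_a_count else 0.0 for c in calls
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_reads",
            "median_tail",
            "mean_tail",
            "frac_reads_with_non_a",
        ],
    )
    global_median = (
        float(statistics.median(df["median_tail"])) if len(df) else None
    )
    return df, global_median


def spikein_calls(
    reads: Iterable[CleanRead],
    spikeins: Sequence[SpikeIn],
    max_barcode_mismatch: int = 1,
    min_a_frac: float = 0.8,
    min_len: int = 5,
) -> tuple[dict[str, list[TailCall]], list[CleanRead]]:
    """Identify spike-in reads by their 3' barcode and call their tails.

    A read matches a spike-in when its insert ends with the spike-in barcode
    (within ``max_barcode_mismatch`` substitutions). The barcode is stripped
    and, when the insert starts with the spike-in's known body sequence, the
    tail is everything after that prefix — the alignment-free analog of a 3'
    soft clip, exact even for tails rich in non-A residues. Reads whose body
    does not match fall back to the suffix heuristic. Returns
    ({spike name: calls}, unmatched reads).
    """
    calls: dict[str, list[TailCall]] = {sp.name: [] for sp in spikeins}
    unmatched: list[CleanRead] = []
    for read in reads:
        hit = None
        for sp in spikeins:
            blen = len(sp.barcode)
            if len(read.insert_seq) < blen:
                continue
            if hamming(read.insert_seq[-blen:], sp.barcode) <= max_barcode_mismatch:
                hit = sp
                break
        if hit is None:
            unmatched.append(read)
            continue
        stripped = read.insert_seq[: -len(hit.barcode)]
        body = hit.reference_seq
        body_tol = max(2, len(body) // 50)
        if (
            len(stripped) >= len(body)
            and hamming(stripped[: len(body)], body) <= body_tol
        ):
            call = _make_call(read.read_id, stripped[len(body) :], "reference_trim")
        else:
            call = call_tail_suffix(stripped, min_a_frac=min_a_frac, min_len=min_len)
            call = TailCall(
                read.read_id,
                call.tail_len,
                call.tail_seq,
                call.non_a_count,
                call.non_a_frac,
                call.method,
            )
        calls[hit.name].append(call)
    return calls, unmatched


def spikein_report(
    calls: Mapping[str, Sequence[TailCall]], spikeins: Sequence[SpikeIn]
) -> pd.DataFrame:
    """Per-spike-in recovery table: n, median/mean measured tail, deviation.

    Spike-ins without reads get n=0 and null medians. Calls under names not
    in ``spikeins`` are pooled into an ``unmatched`` row.
    """
    known = {sp.name for sp in spikeins}
    rows = []
    for sp in spikeins:
        group = calls.get(sp.name, [])
        lengths = [c.tail_len for c in group]
        median = float(statistics.median(lengths)) if lengths else None
        rows.append(
            {
                "name": sp.name,
                "true_tail_len": sp.true_tail_len,
                "n_reads": len(lengths),
                "median_tail": median,
                "mean_tail": statistics.fmean(lengths) if lengths else None,
                "median_deviation": None
                if median is None
                else median - sp.true_tail_len,
            }
        )
    stray = [c for name, group in calls.items() if name not in known for c in group]
    if stray:
        rows.append(
            {
                "name": "unmatched",
                "true_tail_len": None,
                "n_reads": len(stray),
                "median_tail": float(statistics.median(c.tail_len for c in stray)),
                "mean_tail": statistics.fmean(c.tail_len for c in stray),
                "median_deviation": None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name",
            "true_tail_len",
            "n_reads",
            "median_tail",
            "mean_tail",
            "median_deviation",
        ],
    )
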