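"""Greedy poly(A)-site calling and proximal/distal APA-shift statistics.

Read 3' ends scatter by a few nucleotides around the true cleavage position,
so candidate sites (the distinct observed end positions of one gene, pooled
over all samples) are scored by *windowed depth*: the number of read ends
within a centered window (default 5 nt, i.e. +/- 2). Sites are then accepted
greedily — take the deepest remaining candidate, require depth >= 2 and
distance > 15 nt from every accepted site, drop it from the candidate list,
repeat until no candidate reaches the depth floor. Reads are counted at
their nearest accepted site when within 10 bp of it.

Within a gene, the accepted site closest to the stop codon is *proximal*,
the rest *distal*; a shift toward distal usage between two conditions is
tested with a two-sided Fisher's exact test on the 2x2 table of reads within
vs beyond a 50-bp stop-codon cutoff, computed by exact hypergeometric
enumeration (integer arithmetic, no asymptotics).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import GeneModel, distance_to_stop
from .assign import ReadEnd

__all__ = [
    "ApaParams",
    "PolyASite",
    "ApaShiftResult",
    "call_sites",
    "assign_reads_to_sites",
    "label_sites",
    "distal_ratio",
    "fisher_exact",
    "apa_shift_test",
    "apa_distribution",
]


@dataclass(frozen=True)
class ApaParams:
    """Thresholds of the site caller (defaults are the method's values)."""

    depth_window: int = 5
    min_depth: int = 2
    min_site_spacing: int = 15
    assign_radius: int = 10
    stop_codon_cutoff: int = 50
    #: recompute candidate depths after each acceptance (sensitivity mode)
    recompute_depths: bool = False

    def __post_init__(self) -> None:
        for name in ("depth_window", "min_depth", "min_site_spacing", "assign_radius",
                     "stop_codon_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth_window % 2 == 0:
            raise ValueError("depth_window must be odd (window is centered)")


@dataclass
class PolyASite:
    """A called cleavage/polyadenylation site."""

    gene_id: str | None
    chrom: str | None
    strand: str
    pos: int
    windowed_depth: int
    assigned_reads: dict[str, int] = field(default_factory=dict)
    dist_to_stop: int | None = None
    label: str | None = None

    @property
    def total_reads(self) -> int:
        return sum(self.assigned_reads.values())


@dataclass(frozen=True)
class ApaShiftResult:
    """2x2 contingency of near/far-from-stop reads across two conditions."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    continuity_corrected: bool = False


def _windowed_depths(positions: Sequence[int], candidates: Sequence[int],
                     half_window: int) -> list[int]:
    spos = sorted(positions)
    return [
        bisect_right(spos, c + half_window) - bisect_left(spos, c - half_window)
        for c in candidates
    ]


def call_sites(ends: Sequence[ReadEnd], params: ApaParams | None = None) -> list[PolyASite]:
    """Greedy poly(A)-site caller for the pooled read ends of one gene.

    Candidates are the distinct cleavage positions. Each candidate's depth is
    the number of read ends within ``(depth_window - 1) / 2`` nt of it,
    computed once on the full read set. Iteratively, the deepest remaining
    candidate (ties to the smallest genomic coordinate) is accepted iff its
    depth >= ``min_depth`` and it lies more than ``min_site_spacing`` nt from
    every accepted site, then removed from the candidate list; candidates
    within spacing of an accepted site are removed without acceptance. The
    procedure stops when no candidate reaches ``min_depth``. Returned sites
    are sorted by coordinate.
    """
    params = params or ApaParams()
    ends = list(ends)
    if not ends:
        return []
    gene_ids = {e.gene_id for e in ends}
    chroms = {e.chrom for e in ends}
    strands = {e.strand for e in ends}
    if len(chroms) > 1 or len(strands) > 1 or len(gene_ids) > 1:
        raise ValueError("call_sites expects read ends of a single gene")
    positions = [e.cleavage_pos for e in ends]
    half = (params.depth_window - 1) // 2

    candidates = sorted(set(positions))
    depth = dict(zip(candidates, _windowed_depths(positions, candidates, half)))
    remaining = set(candidates)
    accepted: list[tuple[int, int]] = []  # (pos, depth at acceptance)
    while remaining:
        if params.recompute_depths and accepted:
            kept = [
                p
                for p in positions
                if all(abs(p - a) > params.min_site_spacing for a, _ in accepted)
            ]
            cand = sorted(remaining)
            depth = dict(zip(cand, _windowed_depths(kept, cand, half)))
        best = min(remaining, key=lambda c: (-depth[c], c))
        if depth[best] < params.min_depth:
            break
        remaining.discard(best)
        if all(abs(best - a) > params.min_site_spacing for a, _ in accepted):
            accepted.append((best, depth[best]))
        # candidates inside the spacing range of an accepted site can never
        # be accepted; they fall out naturally on later iterations
    gene_id = gene_ids.pop()
    return [
        PolyASite(
            gene_id=gene_id,
            chrom=ends[0].chrom,
            strand=ends[0].strand,
            pos=pos,
            windowed_depth=d,
        )
        for pos, d in sorted(accepted)
    ]


def assign_reads_to_sites(
    ends: Sequence[ReadEnd],
    sites: Sequence[PolyASite],
    params: ApaParams | None = None,
) -> tuple[list[PolyASite], int]:
    """Count each read at its nearest site when within ``assign_radius``.

    Ties between two equidistant sites break to the upstream site in
    transcription direction. Reads farther than the radius from every site
    are unassigned. Returns (sites with per-sample counts, unassigned count).
    """
    params = params or ApaParams()
    for s in sites:
        s.assigned_reads = {}
    unassigned = 0
    if not sites:
        return list(sites), len(ends)
    strand = sites[0].strand
    for e in ends:
        # upstream tie-break: smaller coordinate on +, larger on -
        def key(s: PolyASite):
            upstream = s.pos if strand == "+" else -s.pos
            return (abs(e.cleavage_pos - s.pos), upstream)

        nearest = min(sites, key=key)
        if abs(e.cleavage_pos - nearest.pos) <= params.assign_radius:
            sample = e.sample or "pooled"
            nearest.assigned_reads[sample] = nearest.assigned_reads.get(sample, 0) + 1
        else:
            unassigned += 1
    return list(sites), unassigned


def label_sites(sites: Sequence[PolyASite], gene: GeneModel) -> list[PolyASite]:
    """Attach stop-codon distances and proximal/distal labels.

    The site with the smallest absolute distance to the stop codon is
    proximal; all others are distal. Ties on |distance| break toward the
    upstream site (negative signed distance).
    """
    if not sites:
        return []
    for s in sites:
        s.dist_to_stop = distance_to_stop(gene, s.pos, s.chrom)
    proximal = min(sites, key=lambda s: (abs(s.dist_to_stop), s.dist_to_stop))
    for s in sites:
        s.label = "proximal" if s is proximal else "distal"
    return list(sites)


def distal_ratio(sites: Sequence[PolyASite], sample: str) -> float | None:
    """Fraction of a sample's site-assigned reads landing at distal sites.

    None when the sample has no assigned reads in this gene.
    """
    total = sum(s.assigned_reads.get(sample, 0) for s in sites)
    if total == 0:
        return None
    distal = sum(
        s.assigned_reads.get(sample, 0) for s in sites if s.label == "distal"
    )
    return distal / total


# ---------------------------------------------------------------------------
# Fisher's exact test (exact hypergeometric enumeration)

_REL_SLACK_NUM = 10**7 + 1  # include tables with pmf <= observed * (1 + 1e-7)
_REL_SLACK_DEN = 10**7


def fisher_exact(table: Sequence[Sequence[int]]) -> tuple[float, float, bool]:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums, over all tables with the observed margins, the
    hypergeometric probabilities not exceeding the observed one (with a
    1e-7 relative slack against floating-point ties, as is conventional).
    All probabilities are exact integer ratios; only the final value is a
    float. Returns (odds_ratio, p_value, continuity_corrected): the odds
    ratio is ad/bc, computed with a 0.5 continuity correction (and flagged)
    only when a zero cell makes the plain ratio undefined or zero.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    corrected = 0 in (a, b, c, d)
    if corrected:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return odds, 1.0, corrected
    kmin, kmax = max(0, c1 - r2), min(c1, r1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(kmin, kmax + 1)}
    observed = weights[a]
    kept = sum(
        w
        for w in weights.values()
        if w * _REL_SLACK_DEN <= observed * _REL_SLACK_NUM
    )
    p = float(Fraction(kept, comb(n, c1)))
    return odds, min(p, 1.0), corrected


def apa_shift_test(
    dists_a: Sequence[int],
    dists_b: Sequence[int],
    cutoff: int = 50,
    absolute: bool = True,
) -> ApaShiftResult:
    """Test a proximal/distal APA shift between two conditions.

    ``dists_a`` / ``dists_b`` are read-level signed distances to the stop
    codon. Reads are classified near (|d| <= cutoff; with ``absolute=False``,
    0 <= d <= cutoff) vs far, and the resulting 2x2 table is tested with
    :func:`fisher_exact`.
    """
    if len(dists_a) == 0 or len(dists_b) == 0:
        raise ValueError("both conditions must be non-empty")

    def near(d: int) -> bool:
        return abs(d) <= cutoff if absolute else 0 <= d <= cutoff

    near_a = sum(1 for d in dists_a if near(d))
    near_b = sum(1 for d in dists_b if near(d))
    tab = (
        (near_a, len(dists_a) - near_a),
        (near_b, len(dists_b) - near_b),
    )
    odds, p, corrected = fisher_exact(tab)
    return ApaShiftResult(tab, odds, p, corrected)


def apa_distribution(
    dists: Sequence[int], bin_width: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Density histogram of read distances to the stop codon.

    Bin edges are aligned to multiples of ``bin_width``; densities integrate
    to 1 (sum(density) * bin_width == 1). Empty input yields empty arrays.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    arr = np.asarray(list(dists))
    if arr.size == 0:
        return np.array([]), np.array([])
    lo = int(np.floor(arr.min() / bin_width)) * bin_width
    hi = int(np.floor(arr.max() / bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + 1, bin_width)
    density, _ = np.histogram(arr, bins=edges, density=True)
    return edges, density
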