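"""Independent reference implementations used only to check the package.

These deliberately re-derive results by the most literal route available —
array marking for interval union, a step-by-step replay for the greedy site
caller, brute-force nearest-site search — so they share no code with the
implementations they verify.
"""

from __future__ import annotations


def union_by_marking(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Interval union computed by marking covered integers in an array."""
    if not intervals:
        return []
    lo = min(s for s, _ in intervals)
    hi = max(e for _, e in intervals)
    covered = [False] * (hi - lo)
    for s, e in intervals:
        for i in range(s, e):
            covered[i - lo] = True
    out = []
    start = None
    for i, c in enumerate(covered):
        if c and start is None:
            start = i
        elif not c and start is not None:
            out.append((start + lo, i + lo))
            start = None
    if start is not None:
        out.append((start + lo, hi))
    return out


def replay_greedy(
    positions: list[int],
    window: int = 5,
    min_depth: int = 2,
    spacing: int = 15,
) -> list[int]:
    """Literal replay of the greedy site-calling rules.

    Depths are computed once per candidate by counting reads within the
    centered window; each round the deepest remaining candidate (smallest
    coordinate on ties) is taken, removed, and accepted when it is more than
    ``spacing`` nt from every accepted site; the loop ends when the deepest
    remaining candidate is below ``min_depth``.
    """
    half = (window - 1) // 2
    candidates = sorted(set(positions))
    depth = {c: sum(1 for p in positions if abs(p - c) <= half) for c in candidates}
    remaining = list(candidates)
    accepted: list[int] = []
    while remaining:
        best = remaining[0]
        for c in remaining[1:]:
            if depth[c] > depth[best] or (depth[c] == depth[best] and c < best):
                best = c
        if depth[best] < min_depth:
            break
        remaining.remove(best)
        if all(abs(best - a) > spacing for a in accepted):
            accepted.append(best)
    return sorted(accepted)


def nearest_site_bruteforce(
    read_pos: int, site_positions: list[int], strand: str, radius: int
) -> int | None:
    """Brute-force nearest-site assignment with the upstream tie-break."""
    best = None
    for s in site_positions:
        if best is None:
            best = s
            continue
        d_new, d_best = abs(read_pos - s), abs(read_pos - best)
        if d_new < d_best:
            best = s
        elif d_new == d_best:
            upstream = min if strand == "+" else max
            best = upstream(best, s)
    if best is None or abs(read_pos - best) > radius:
        return None
    return best


def suffix_tail_bruteforce(seq: str, min_a_frac: float, min_len: int) -> int:
    """Longest A-led suffix with A-fraction >= min_a_frac, by full scan."""
    n = len(seq)
    best = 0
    for start in range(n):
        suffix = seq[start:]
        if not suffix.startswith("A"):
            continue
        if suffix.count("A") >= min_a_frac * len(suffix):
            best = len(suffix)
            break  # first (longest) valid suffix wins
    return best if best >= min_len else 0
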