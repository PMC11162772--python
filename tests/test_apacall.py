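import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given
from hypothesis import strategies as hs

from bowlseq.annotation import GeneModel
from bowlseq.apacall import (
    ApaParams,
    apa_distribution,
    apa_shift_test,
    assign_reads_to_sites,
    call_sites,
    distal_ratio,
    fisher_exact,
    label_sites,
)
from bowlseq.assign import ReadEnd
from oracles import nearest_site_bruteforce, replay_greedy


def _ends(positions, strand="+", sample="s1"):
    return [
        ReadEnd(f"r{i}", "chr1", strand, p, tail_len=20, sample=sample, gene_id="g")
        for i, p in enumerate(positions)
    ]


def test_worked_example_two_sites_with_counts():
    """Ends {100x3, 104x2, 130x2, 131x1}: sites at 100 and 130; 104/131
    suppressed by spacing; all 8 reads counted (5 + 3)."""
    ends = _ends([100] * 3 + [104] * 2 + [130] * 2 + [131])
    sites = call_sites(ends)
    assert [(s.pos, s.windowed_depth) for s in sites] == [(100, 3), (130, 3)]
    sites, unassigned = assign_reads_to_sites(ends, sites)
    assert [(s.pos, s.total_reads) for s in sites] == [(100, 5), (130, 3)]
    assert unassigned == 0


def test_single_read_below_depth_floor_calls_nothing():
    assert call_sites(_ends([200])) == []
    assert call_sites([]) == []


@given(
    hs.lists(hs.integers(0, 499), min_size=1, max_size=60),
)
def test_greedy_matches_replay_oracle(positions):
    ends = _ends(positions)
    called = [s.pos for s in call_sites(ends)]
    assert called == replay_greedy(positions)
    # post-hoc invariants on every output
    for s in call_sites(ends):
        assert s.windowed_depth >= 2
    for a in called:
        for b in called:
            assert a == b or abs(a - b) > 15


def test_calling_is_invariant_to_read_order_and_sample_labels():
    rng = np.random.default_rng(3)
    positions = rng.integers(0, 400, size=50).tolist()
    base = [s.pos for s in call_sites(_ends(positions))]
    shuffled = positions[::-1]
    assert [s.pos for s in call_sites(_ends(shuffled))] == base
    relabeled = _ends(positions, sample="other")
    assert [s.pos for s in call_sites(relabeled)] == base


def test_mixed_gene_input_rejected():
    ends = _ends([100, 100])
    ends[1].gene_id = "other"
    with pytest.raises(ValueError):
        call_sites(ends)


@pytest.mark.parametrize(
    "read_pos, expected_site",
    [
        (140, 130),  # distance 10, inclusive
        (141, None),  # distance 11 > radius -> unassigned
        (95, 100),
        (89, None),
    ],
)
def test_assignment_radius_is_inclusive(read_pos, expected_site):
    ends = _ends([100] * 2 + [130] * 2 + [read_pos])
    sites = call_sites(ends)
    assert [s.pos for s in sites] == [100, 130]
    sites, unassigned = assign_reads_to_sites(ends, sites)
    if expected_site is None:
        assert unassigned == 1
    else:
        assert unassigned == 0


@pytest.mark.parametrize("strand, winner", [("+", 100), ("-", 120)])
def test_equidistant_tie_breaks_upstream(strand, winner):
    ends = _ends([100] * 2 + [120] * 2 + [110], strand=strand)
    # default spacing (15) would suppress the second site; shrink it
    params = ApaParams(min_site_spacing=9)
    sites = call_sites(ends, params)
    assert [s.pos for s in sites] == [100, 120]
    sites, _ = assign_reads_to_sites(ends, sites, params)
    by_pos = {s.pos: s.total_reads for s in sites}
    assert by_pos[winner] == 3
    assert nearest_site_bruteforce(110, [100, 120], strand, 10) == winner


def _gene(strand="+", stop=1000):
    return GeneModel.from_exons("g", "chr1", strand, [(500, 2000)], stop)


def test_label_sites_proximal_is_nearest_to_stop():
    ends = _ends([1030] * 2 + [1400] * 2)
    sites = call_sites(ends)
    label_sites(sites, _gene())
    assert [(s.pos, s.label) for s in sites] == [
        (1030, "proximal"),
        (1400, "distal"),
    ]
    assert [s.dist_to_stop for s in sites] == [30, 400]


def test_label_single_site_is_proximal():
    sites = call_sites(_ends([1200] * 3))
    label_sites(sites, _gene())
    assert sites[0].label == "proximal"


def test_label_tie_on_abs_distance_goes_upstream():
    ends = _ends([960] * 2 + [1040] * 2)
    sites = call_sites(ends)
    label_sites(sites, _gene())
    labels = {s.pos: s.label for s in sites}
    assert labels == {960: "proximal", 1040: "distal"}  # -40 beats +40


@pytest.mark.parametrize(
    "counts, expected",
    [({"proximal": 5, "distal": 3}, 0.375), ({"proximal": 4}, 0.0),
     ({"distal": 7}, 1.0)],
)
def test_distal_ratio(counts, expected):
    ends = _ends([1030] * 2 + [1400] * 2)
    sites = call_sites(ends)
    label_sites(sites, _gene())
    for s in sites:
        s.assigned_reads = {"s1": counts.get(s.label, 0)}
    assert distal_ratio(sites, "s1") == expected
    assert distal_ratio(sites, "missing_sample") is None


# ---------------------------------------------------------------------------
# Fisher's exact test


def test_fisher_symmetric_table_is_exactly_one():
    assert fisher_exact([[1, 1], [1, 1]])[1] == 1.0


def test_fisher_diagonal_table_matches_enumeration():
    from math import comb

    _, p, _ = fisher_exact([[10, 0], [0, 10]])
    assert p == pytest.approx(2 / comb(20, 10), abs=1e-15)


@given(
    hs.tuples(*(hs.integers(0, 25) for _ in range(4))),
)
def test_fisher_matches_scipy(cells):
    a, b, c, d = cells
    _, p, _ = fisher_exact([[a, b], [c, d]])
    assert p == pytest.approx(st.fisher_exact([[a, b], [c, d]])[1], abs=1e-12)


def test_fisher_odds_ratio_and_continuity_flag():
    odds, _, corrected = fisher_exact([[8, 2], [4, 6]])
    assert odds == pytest.approx(6.0) and not corrected
    odds0, _, corrected0 = fisher_exact([[8, 0], [4, 6]])
    assert corrected0 and odds0 > 1


def test_shift_test_identical_distances_give_p_one():
    dists = [20] * 30 + [300] * 20
    res = apa_shift_test(dists, list(dists))
    assert res.p_value == 1.0
    assert res.table[0] == res.table[1]


def test_shift_test_classifies_by_absolute_distance():
    res = apa_shift_test([-40, 40, 200], [51, -51, 300], cutoff=50)
    assert res.table == ((2, 1), (0, 3))


def test_shift_test_empty_condition_errors():
    with pytest.raises(ValueError):
        apa_shift_test([], [1, 2])


# ---------------------------------------------------------------------------
# distance histogram


def test_distribution_single_point_mass():
    edges, density = apa_distribution([0] * 10, bin_width=10)
    assert len(density) == 1
    assert density[0] * 10 == pytest.approx(1.0)


def test_distribution_uniform_bins():
    dists = list(range(100))
    edges, density = apa_distribution(dists, bin_width=10)
    assert len(density) == 10
    assert np.allclose(density, density[0])
    assert np.sum(density) * 10 == pytest.approx(1.0)


@given(hs.lists(hs.integers(-400, 400), min_size=1, max_size=200),
       hs.sampled_from([1, 5, 10, 25]))
def test_distribution_integrates_to_one(dists, bin_width):
    _, density = apa_distribution(dists, bin_width)
    assert np.sum(density) * bin_width == pytest.approx(1.0)


def test_distribution_empty_input():
    edges, density = apa_distribution([], 10)
    assert edges.size == 0 and density.size == 0
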