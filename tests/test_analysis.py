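import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shagcarpet.analysis import (
    compare_polarity,
    group_top_fraction,
    hodges_lehmann_shift,
    ranksum_median_ci,
    summarize,
)
from shagcarpet.edge_detect import Edge, EdgeSet


def _edge(tt, center=50.0, included=True):
    return Edge(
        center_time=center, polarity="rising", rows=np.arange(2),
        times=np.zeros(2), slope=0.0, intercept=0.0, transit_time=tt,
        r_squared=1.0, contrast=1.0, rate=1.0, included=included,
    )


def _edgeset(tts, centers=None):
    centers = centers or [50.0 + 10 * i for i in range(len(tts))]
    return EdgeSet(edges=[_edge(t, c) for t, c in zip(tts, centers)])


class TestSummarize:
    def test_constant_transits(self):
        s = summarize(_edgeset([4.0, 4.0, 4.0]))
        assert s.mean_s == pytest.approx(4.0)
        assert s.sd_s == pytest.approx(0.0)
        assert s.negatives == 0

    def test_negative_count(self):
        s = summarize(_edgeset([3.0, -1.0]))
        assert s.negatives == 1

    def test_excluded_edges_ignored(self):
        es = EdgeSet(edges=[_edge(4.0), _edge(100.0, included=False)])
        assert summarize(es).n_edges == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(EdgeSet(edges=[_edge(1.0, included=False)]))


class TestGroupTopFraction:
    def _signal(self):
        t = np.arange(300) * 1.0
        g = np.sin(2 * np.pi * 0.02 * t)
        g[140:160] += 3.0  # one dominant peak at ~150 s
        return g

    def test_near_unit_fraction_includes_all(self):
        es = _edgeset([4.0, 4.1, 3.9], centers=[40.0, 140.0, 240.0])
        df = group_top_fraction(es, self._signal(), 1.0, fraction=0.999)
        assert (df["group"] == "top_fraction").all()

    def test_tiny_fraction_excludes_all_but_dominant(self):
        es = _edgeset([4.0, 4.1, 3.9], centers=[40.0, 140.0, 240.0])
        df = group_top_fraction(es, self._signal(), 1.0, fraction=0.05)
        assert df.set_index("center_time_s")["group"].to_dict() == {
            40.0: "remainder", 140.0: "top_fraction", 240.0: "remainder",
        }

    def test_invalid_fraction(self):
        es = _edgeset([4.0])
        with pytest.raises(ValueError):
            group_top_fraction(es, self._signal(), 1.0, fraction=1.5)


def exact_ranksum_ci(a, b, alpha=0.05):
    """Oracle: CI cut rank from exhaustive enumeration of the exact
    Mann-Whitney U distribution (all C(m+n, m) label assignments)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    m, n = len(a), len(b)
    mn = m * n
    # exact null distribution of U via enumeration of rank subsets
    ranks = np.arange(1, m + n + 1)
    us = []
    for comb in itertools.combinations(range(m + n), m):
        u = sum(ranks[list(comb)]) - m * (m + 1) / 2
        us.append(u)
    us = np.array(us)
    total = len(us)
    # largest k such that P(U <= k - 1) <= alpha/2
    k = 0
    for cand in range(1, mn + 1):
        if np.sum(us <= cand - 1) / total <= alpha / 2:
            k = cand
        else:
            break
    k = max(1, k)
    diffs = np.sort(np.subtract.outer(a, b).ravel())
    return float(diffs[k - 1]), float(diffs[mn - k])


class TestRanksumMedianCI:
    def test_identical_samples_contains_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        lo, hi = ranksum_median_ci(a, a)
        assert lo <= 0.0 <= hi

    def test_location_shift_equivariance(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 2.0
        lo, hi = ranksum_median_ci(a, b)
        assert (lo + hi) / 2 == pytest.approx(-2.0, abs=0.5)
        lo2, hi2 = ranksum_median_ci(a + 5.0, b)
        assert lo2 == pytest.approx(lo + 5.0)
        assert hi2 == pytest.approx(hi + 5.0)

    @pytest.mark.parametrize("m,n", [(2, 5), (3, 3), (3, 5), (4, 4), (4, 5), (5, 5)])
    def test_matches_exact_enumeration_oracle(self, m, n):
        rng = np.random.default_rng(m * 10 + n)
        a = rng.normal(0.0, 1.0, m)
        b = rng.normal(1.0, 1.0, n)
        assert ranksum_median_ci(a, b) == exact_ranksum_ci(a, b)

    def test_degenerate_equal_samples_warn(self):
        with pytest.warns(UserWarning):
            lo, hi = ranksum_median_ci([2.0, 2.0], [2.0, 2.0])
        assert lo == hi == 0.0

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            ranksum_median_ci([1.0], [1.0, 2.0])

    def test_coverage_simulation(self):
        """95% CI covers a true median shift in ~95% of repeated draws."""
        rng = np.random.default_rng(2024)
        shift = 1.0
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(shift, 1.0, 12)
            b = rng.normal(0.0, 1.0, 12)
            lo, hi = ranksum_median_ci(a, b)
            hits += lo <= shift <= hi
        assert 0.93 <= hits / n_sim <= 0.97


def test_hodges_lehmann_point_estimate():
    a = np.array([1.0, 2.0, 3.0])
    assert hodges_lehmann_shift(a + 2.0, a) == pytest.approx(2.0)


class TestComparePolarity:
    def test_identical_groups(self):
        r = compare_polarity([4.0, 5.0, 6.0], [4.0, 5.0, 6.0])
        assert r.t_statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_disjoint_constant_groups(self):
        r = compare_polarity([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert r.p_value < 0.01

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(4.0, 1.0, 15)
        b = rng.normal(4.5, 1.0, 12)
        r = compare_polarity(a, b)
        # permutation distribution of the mean difference
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        n_perm = 3000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            count += abs(perm[:15].mean() - perm[15:].mean()) >= obs
        p_perm = count / n_perm
        assert abs(r.p_value - p_perm) < 0.05

    def test_accepts_edgesets(self):
        r = compare_polarity(_edgeset([4.0, 5.0]), _edgeset([4.0, 5.0]))
        assert r.n_a == r.n_b == 2

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_polarity([1.0], [1.0, 2.0])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    shift=st.floats(-3.0, 3.0),
)
def test_ci_shift_equivariance_property(seed, shift):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=8)
    b = rng.normal(size=9)
    lo, hi = ranksum_median_ci(a, b)
    lo2, hi2 = ranksum_median_ci(a + shift, b)
    assert lo2 == pytest.approx(lo + shift, abs=1e-9)
    assert hi2 == pytest.approx(hi + shift, abs=1e-9)
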