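"""Nonparametric tests against brute-force enumeration and scipy oracles."""

from itertools import combinations, product

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as hst

from nephna.core import DataError
from nephna import stats as st


# ---------------------------------------------------------------------------
# independent brute-force oracles

def brute_wilcoxon_p(d):
    """Two-sided signed-rank p by explicit iteration over sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    hits = total = 0
    for signs in product([0, 1], repeat=len(d)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def brute_ranksum_p(a, b):
    """Two-sided rank-sum p by explicit iteration over group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, n = len(a), len(a) + len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    r_obs = ranks[:na].sum()
    mu = na * (n + 1) / 2.0
    hits = total = 0
    for idx in combinations(range(n), na):
        r = ranks[list(idx)].sum()
        total += 1
        if abs(r - mu) >= abs(r_obs - mu) - 1e-12:
            hits += 1
    return hits / total


SIGNED_RANK_CASES = [
    [1, 2, 3, 4, 5],
    [-1, 2, -3, 4, 5],
    [1, 1, 2, -2, 3],           # tied |d|
    [0.5, -0.5, 1.5, 2.5, -2.5, 3.5],
    [2, 2, 2, -1, -1, 3, 4],
    [1, -2, 3, -4, 5, -6, 7, -8, 9],
    [0.1, 0.1, 0.1, -0.2, 0.3, -0.3, 0.4, 0.5, -0.5, 0.6],
]

RANKSUM_CASES = [
    ([1, 2], [3, 4]),
    ([1, 2, 3], [1, 2, 3]),
    ([1, 1, 2], [2, 3, 3]),     # cross-group ties
    ([5, 7, 9, 11], [6, 8, 10]),
    ([1, 2, 3, 4, 5], [2, 2, 6, 7, 8]),
    ([10, 20, 30], [11, 21, 31, 41]),
]


class TestWilcoxonSignedRank:
    def test_identical_pairs_degenerate(self):
        res = st.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert "zero" in res.note

    def test_frozen_all_positive_n5(self):
        """Differences {1..5}: W+ = 15, exact two-sided p = 2/32."""
        res = st.wilcoxon_signed_rank([2, 4, 6, 8, 10], [1, 2, 3, 4, 5])
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(2.0 / 32.0)

    @pytest.mark.parametrize("d", SIGNED_RANK_CASES)
    def test_matches_brute_force(self, d):
        res = st.wilcoxon_signed_rank(np.asarray(d, float), np.zeros(len(d)))
        assert res.p_value == pytest.approx(brute_wilcoxon_p(d))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        d = np.round(rng.normal(0.3, 1.0, n), 1)
        d = d[d != 0]
        if len(d) < 3:
            pytest.skip("degenerate draw")
        res = st.wilcoxon_signed_rank(d, np.zeros(len(d)))
        assert res.p_value == pytest.approx(brute_wilcoxon_p(d))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_tie_free(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.normal(0.5, 1.0, 9)  # continuous: no ties, no zeros
        ours = st.wilcoxon_signed_rank(d, np.zeros(9))
        ref = sps.wilcoxon(d, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_approx_mode_close_to_exact(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.8, 1.0, 12)
        p_exact = st.wilcoxon_signed_rank(d, np.zeros(12), mode="exact").p_value
        p_approx = st.wilcoxon_signed_rank(d, np.zeros(12), mode="approx").p_value
        assert p_approx == pytest.approx(p_exact, abs=0.02)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            st.wilcoxon_signed_rank([1, 2], [1, 2, 3])


class TestRankSum:
    def test_identical_groups_maximal_p(self):
        res = st.rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_frozen_extreme_case(self):
        """{1,2} vs {3,4}: U = 0, p = 2/6 over the C(4,2) splits."""
        res = st.rank_sum([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2.0 / 6.0)

    @pytest.mark.parametrize("a,b", RANKSUM_CASES)
    def test_matches_brute_force(self, a, b):
        res = st.rank_sum(np.asarray(a, float), np.asarray(b, float))
        assert res.p_value == pytest.approx(brute_ranksum_p(a, b))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_random(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 6, 2)
        a = np.round(rng.normal(0, 1, na), 1)
        b = np.round(rng.normal(0.5, 1, nb), 1)
        res = st.rank_sum(a, b)
        assert res.p_value == pytest.approx(brute_ranksum_p(a, b))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_tie_free(self, seed):
        rng = np.random.default_rng(200 + seed)
        a, b = rng.normal(0, 1, 5), rng.normal(0.7, 1, 6)
        ours = st.rank_sum(a, b)
        ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_too_small(self):
        with pytest.raises(DataError):
            st.rank_sum([1.0], [2.0, 3.0])


class TestKruskalWallis:
    def test_hand_computed_h(self):
        """{1,2},{3,4},{5,6}: H = 32/7 by the rank formula."""
        res = st.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32.0 / 7.0)

    def test_degenerate_identical(self):
        res = st.kruskal_wallis([[5.0, 5.0], [5.0, 5.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert "degenerate" in res.note

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        gs = [rng.normal(m, 1, rng.integers(3, 8)) for m in (0.0, 0.5, 1.0)]
        ours = st.kruskal_wallis(gs)
        ref = sps.kruskal(*gs)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_too_few_groups(self):
        with pytest.raises(DataError):
            st.kruskal_wallis([[1, 2, 3]])


class TestBonferroni:
    def test_hand_cases(self):
        assert st.bonferroni_adjust([0.04], m=1)[0] == pytest.approx(0.04)
        assert st.bonferroni_adjust([0.01], m=3)[0] == pytest.approx(0.03)
        assert st.bonferroni_adjust([0.5], m=3)[0] == 1.0  # capped

    def test_m_too_small(self):
        with pytest.raises(DataError):
            st.bonferroni_adjust([0.1, 0.2, 0.3], m=2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.lists(hst.floats(0.0, 1.0), min_size=1, max_size=8),
           hst.integers(0, 10))
    def test_never_decreases_and_stays_valid(self, ps, extra):
        adj = st.bonferroni_adjust(ps, m=len(ps) + extra)
        assert np.all(adj >= np.asarray(ps))
        assert np.all((adj >= 0) & (adj <= 1))


class TestCovAndLinearFit:
    def test_cov_hand_cases(self):
        assert st.cov_percent([7.0, 7.0, 7.0]) == 0.0
        assert st.cov_percent([90.0, 100.0, 110.0]) == pytest.approx(10.0)

    def test_cov_zero_mean(self):
        with pytest.raises(DataError):
            st.cov_percent([-1.0, 1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.floats(0.01, 100.0), hst.integers(0, 2 ** 31 - 1))
    def test_cov_scale_invariant(self, scale, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(50, 150, 6)
        assert st.cov_percent(scale * v) == pytest.approx(st.cov_percent(v))

    def test_collinear_r2(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = st.linear_fit_r2(x, 2.0 * x + 1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_hand_normal_equations(self):
        """{(0,0),(1,1),(2,3)}: slope 3/2, intercept -1/6, R^2 = 27/28."""
        fit = st.linear_fit_r2([0.0, 1.0, 2.0], [0.0, 1.0, 3.0])
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(-1.0 / 6.0)
        assert fit.r_squared == pytest.approx(27.0 / 28.0)

    def test_scale_offset_insensitive_r2(self):
        """A 2x offset between modalities leaves the correlation intact."""
        rng = np.random.default_rng(5)
        x = np.array([39.0, 22.0, 41.0, 20.0]) + rng.normal(0, 1, 4)
        y = 2.0 * x + rng.normal(0, 2, 4)
        fit = st.linear_fit_r2(x, y)
        assert fit.r_squared > 0.9

    def test_constant_x(self):
        with pytest.raises(DataError):
            st.linear_fit_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_all_p_values_in_unit_interval():
    rng = np.random.default_rng(9)
    for _ in range(20):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.3, 1, 6)
        for res in (st.wilcoxon_signed_rank(a, b), st.rank_sum(a, b),
                    st.kruskal_wallis([a, b])):
            assert 0.0 <= res.p_value <= 1.0
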