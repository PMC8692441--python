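"""Statistical battery vs independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from loyscan import (
    bh_adjust,
    fit_linear_model,
    kruskal_wallis,
    location_test_vs_zero,
    spearman_corr,
    two_sample_rank_test,
)
from loyscan.errors import DegenerateInputError, ValidationError

# ---------------------------------------------------------------------------
# Enumeration oracles (independent of the implementation paths they check)


def signed_rank_enumeration_p(values):
    """Two-sided exact p for the one-sample signed-rank test by direct
    enumeration of all 2^n sign assignments (zeros dropped, midranks)."""
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    n = len(v)
    ranks = sps.rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product([-1, 1], repeat=n)
    ]
    ws = np.asarray(ws)
    eps = 1e-9
    p_le = np.mean(ws <= w_obs + eps)
    p_ge = np.mean(ws >= w_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


def mwu_enumeration_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all C(n+m, n)
    assignments of the pooled ranks to the first group."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    m = len(pooled)
    mu = n * (len(y)) / 2.0
    us = [
        ranks[list(idx)].sum() - n * (n + 1) / 2.0
        for idx in itertools.combinations(range(m), n)
    ]
    us = np.asarray(us)
    eps = 1e-9
    return min(1.0, float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - eps)))


def bh_step_up(p):
    """Direct step-up formula: q_(i) = min_{j>=i} p_(j) * m / j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


# ---------------------------------------------------------------------------
# Signed-rank test


class TestLocationTestVsZero:
    @pytest.mark.parametrize(
        "values,expected_p",
        [
            ([1, 2, 3], 0.25),
            ([-5, 5], 1.0),
            ([1, 2, 3, 4, 5, 6], 2 / 64),
        ],
    )
    def test_exact_examples(self, values, expected_p):
        res = location_test_vs_zero(values)
        assert res.method_detail == "exact"
        assert res.p_value == pytest.approx(expected_p)

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        # mix of continuous values, ties and zeros
        v = rng.choice([-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0], size=n)
        if not np.any(v):
            v[0] = 1.0
        res = location_test_vs_zero(v)
        assert res.p_value == pytest.approx(signed_rank_enumeration_p(v), abs=1e-12)

    def test_zeros_dropped_reduce_n(self):
        res = location_test_vs_zero([0.0, 0.0, 1.0, 2.0, 3.0])
        assert res.n == (3,)
        assert res.p_value == pytest.approx(0.25)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            location_test_vs_zero([0.0, 0.0])

    def test_large_n_uses_continuity_corrected_normal(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0.3, 1.0, size=40)
        res = location_test_vs_zero(v)
        assert res.method_detail == "approximate"
        # cross-check against scipy's continuity-corrected approximation
        ref = sps.wilcoxon(v, correction=True, mode="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_symmetric_null_rate_is_nominal(self):
        rng = np.random.default_rng(11)
        rejections = sum(
            location_test_vs_zero(rng.normal(0, 1, size=12)).p_value < 0.05
            for _ in range(400)
        )
        assert 0.01 <= rejections / 400 <= 0.10


# ---------------------------------------------------------------------------
# Mann-Whitney


class TestTwoSampleRankTest:
    @pytest.mark.parametrize(
        "x,y,expected_p",
        [
            ([1, 2], [3, 4], 1 / 3),
            ([1], [2], 1.0),
        ],
    )
    def test_exact_examples(self, x, y, expected_p):
        res = two_sample_rank_test(x, y)
        assert res.method_detail == "exact"
        assert res.p_value == pytest.approx(expected_p)

    def test_identical_multisets_give_p_one(self):
        res = two_sample_rank_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, m = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        pooled = rng.permutation(np.arange(1.0, n + m + 1))  # tie-free
        x, y = pooled[:n], pooled[n:]
        res = two_sample_rank_test(x, y)
        assert res.method_detail == "exact"
        assert res.p_value == pytest.approx(mwu_enumeration_p(x, y), abs=1e-12)

    def test_ties_switch_to_approximation(self):
        res = two_sample_rank_test([1, 2, 2], [2, 3, 4])
        assert res.method_detail == "approximate"

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            two_sample_rank_test([], [1.0])


# ---------------------------------------------------------------------------
# BH correction


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([0.04, 0.9], [0.08, 0.9]),
        ],
    )
    def test_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_step_up_formula(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
        assert bh_adjust(p) == pytest.approx(bh_step_up(p), abs=1e-12)

    def test_invariants(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, size=25)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)  # never decreases
        assert np.all((0 <= q) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # order-preserving

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# Linear model


class TestFitLinearModel:
    def test_exact_line(self):
        fit = fit_linear_model([2, 4, 6], [1, 2, 3])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_response(self):
        fit = fit_linear_model([5, 5, 5], [1, 2, 3])
        assert fit.slope == pytest.approx(0.0)

    def test_closed_form_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        fit = fit_linear_model(y, x)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_slope_p_matches_t_distribution(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        fit = fit_linear_model(y, x)
        resid = y - (fit.intercept + fit.slope * x)
        se = math.sqrt(resid @ resid / 18 / ((x - x.mean()) @ (x - x.mean())))
        p = 2 * sps.t.sf(abs(fit.slope / se), df=18)
        assert fit.slope_p == pytest.approx(p, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_linear_model([1, 2, 3], [5, 5, 5])


# ---------------------------------------------------------------------------
# Kruskal-Wallis


class TestKruskalWallis:
    def test_identical_groups_no_separation(self):
        res = kruskal_wallis([[1, 2], [1, 2]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_rank_formula_value(self):
        # ranks 1..6 in three groups: H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1)
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        h = 12 / (6 * 7) * (3**2 / 2 + 7**2 / 2 + 11**2 / 2) - 3 * 7
        assert res.statistic == pytest.approx(h)
        assert h == pytest.approx(32 / 7)

    def test_two_groups_equal_mwu_without_continuity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        y = rng.normal(0.5, 1, size=9)
        kw = kruskal_wallis([x, y])
        mwu = two_sample_rank_test(x, y, continuity=False)
        assert kw.p_value == pytest.approx(mwu.p_value, abs=1e-6)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2, 3]])


# ---------------------------------------------------------------------------
# Spearman


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman_corr([1, 2, 3, 4], [10, 20, 30, 40]).statistic == 1.0

    def test_monotone_decreasing(self):
        assert spearman_corr([1, 2, 3, 4], [4, 3, 2, 1]).statistic == -1.0

    def test_exact_p_matches_permutation_enumeration(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman_corr(x, y)
        assert res.method_detail == "exact"
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rho_obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = sum(
            abs(np.corrcoef(rx, perm)[0, 1]) >= rho_obs - 1e-12
            for perm in itertools.permutations(ry)
        )
        assert res.p_value == pytest.approx(hits / math.factorial(6), abs=1e-12)

    def test_large_n_t_approximation(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = spearman_corr(x, y)
        assert res.method_detail == "approximate"
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman_corr([1, 1, 1], [1, 2, 3])
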