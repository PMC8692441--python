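"""Rank-based hypothesis tests, BH correction, and simple linear fits.

The battery used by the LOY screens:

* :func:`location_test_vs_zero` — one-sample Wilcoxon signed-rank test
  of symmetric location 0 (the "is this group's dosage score centered at
  parity?" test). Exact null distribution by enumeration for n <= 25
  (zeros dropped, ties midranked), tie-corrected normal approximation
  with continuity correction above that.
* :func:`two_sample_rank_test` — two-sided Mann-Whitney U (young vs old
  comparisons); exact for min(n) <= 8 without ties.
* :func:`bh_adjust` — Benjamini-Hochberg step-up FDR correction.
* :func:`fit_linear_model` — OLS with the two-sided t-test on the slope.
* :func:`kruskal_wallis` — tie-corrected H with a chi-squared p.
* :func:`spearman_corr` — midrank Spearman rho; exact permutation p for
  n <= 7, t approximation otherwise.

``method_detail`` on every result records whether the exact or the
approximate path ran, since small LOY cohorts routinely sit on the
boundary where the two differ.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ValidationError

EXACT = "exact"
APPROX = "approximate"

#: Exactness thresholds: chosen so the exact paths enumerate in
#: milliseconds at desk scale while covering typical cohort sizes.
SIGNED_RANK_EXACT_MAX_N = 25
MWU_EXACT_MAX_MIN_N = 8
SPEARMAN_EXACT_MAX_N = 7


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method_detail: str
    group_labels: tuple[str, ...] | None = None


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    slope_p: float
    r_squared: float
    n: int


# ---------------------------------------------------------------------------
# One-sample signed-rank test


def _signed_rank_exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ by dynamic programming over sign flips.

    Midranks are doubled to integers; the distribution of 2*W+ over all
    2^n equiprobable sign assignments is built by convolution (array
    length <= n(n+1)+1, trivial for n <= 25). Two-sided p is
    min(1, 2*min(P(W <= w), P(W >= w))), the R convention.
    """
    d = np.rint(2.0 * ranks).astype(np.int64)
    total = int(d.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in d:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= 2.0 ** len(d)
    w2 = int(round(2.0 * w_plus))
    p_le = float(counts[: w2 + 1].sum())
    p_ge = float(counts[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def location_test_vs_zero(values) -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank test of location 0.

    Zeros are dropped before ranking (the R wilcox.test convention; note
    this reduces n), absolute values are midranked under ties, and the
    statistic is W+, the sum of ranks of the positive values. Exact
    enumeration for n <= 25 even under ties; otherwise a tie-corrected
    normal approximation with continuity correction.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValidationError("values: need a non-empty 1-d array")
    if not np.all(np.isfinite(v)):
        raise ValidationError("values: must be finite")
    v = v[v != 0.0]
    n = len(v)
    if n == 0:
        raise DegenerateInputError("all values are zero; signed-rank test undefined")
    ranks = sps.rankdata(np.abs(v))
    w_plus = float(ranks[v > 0].sum())
    if n <= SIGNED_RANK_EXACT_MAX_N:
        p = _signed_rank_exact_two_sided_p(ranks, w_plus)
        detail = EXACT
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(
            ((tie_counts**3 - tie_counts) / 48.0).sum()
        )
        if sigma2 <= 0:
            raise DegenerateInputError("zero variance in signed-rank approximation")
        z = w_plus - mu
        z -= math.copysign(0.5, z) if z != 0 else 0.0
        z /= math.sqrt(sigma2)
        p = 2.0 * float(sps.norm.sf(abs(z)))
        detail = APPROX
    return TestResult(
        test_name="wilcoxon_signed_rank_vs_zero",
        statistic=w_plus,
        p_value=min(1.0, p),
        n=(n,),
        method_detail=detail,
    )


# ---------------------------------------------------------------------------
# Two-sample rank test


def two_sample_rank_test(x, y, continuity: bool = True) -> TestResult:
    """Two-sided Mann-Whitney U test (unpaired).

    Exact when min(n) <= 8 and the pooled data has no ties; otherwise a
    tie-corrected normal approximation (continuity-corrected by default,
    as in R). The statistic is U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("x, y: both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(x), len(y)) <= MWU_EXACT_MAX_MIN_N and not has_ties
    res = sps.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=continuity,
    )
    return TestResult(
        test_name="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(x), len(y)),
        method_detail=EXACT if exact else APPROX,
    )


# ---------------------------------------------------------------------------
# Multiple testing


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values: need a 1-d array")
    if len(p) == 0:
        return np.array([])
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p_values: all values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Linear model


def fit_linear_model(y, x) -> LinearFit:
    """OLS of y on x; slope p from the two-sided t-test with n-2 df."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x, y: lengths differ")
    if len(x) < 3:
        raise ValidationError("n: need at least 3 points for a slope p-value")
    if np.ptp(x) == 0:
        raise DegenerateInputError("x is constant; slope is not identifiable")
    res = sps.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_p=float(res.pvalue),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def kruskal_wallis(groups, labels=None) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared(k-1) p-value.

    Groups with identical pooled values (no separation possible) yield
    H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("groups: need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("groups: all groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        res = sps.kruskal(*groups)
        h, p = float(res.statistic), float(res.pvalue)
    return TestResult(
        test_name="kruskal_wallis",
        statistic=h,
        p_value=p,
        n=tuple(len(g) for g in groups),
        method_detail=APPROX,
        group_labels=tuple(labels) if labels is not None else None,
    )


# ---------------------------------------------------------------------------
# Spearman correlation


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_corr(x, y) -> TestResult:
    """Two-sided Spearman rank correlation (rho = Pearson of midranks).

    Exact p by full permutation enumeration for n <= 7 (valid under
    ties); t approximation with n-2 df otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x, y: lengths differ")
    n = len(x)
    if n < 3:
        raise ValidationError("n: need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input; rank correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= SPEARMAN_EXACT_MAX_N:
        target = abs(rho) - 1e-12
        hits = sum(
            abs(_rank_corr(rx, np.asarray(perm))) >= target
            for perm in itertools.permutations(ry)
        )
        p = hits / math.factorial(n)
        detail = EXACT
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
        detail = APPROX
    return TestResult(
        test_name="spearman_rho",
        statistic=rho,
        p_value=min(1.0, p),
        n=(n,),
        method_detail=detail,
    )
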