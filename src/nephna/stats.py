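"""Nonparametric statistics for the reproducibility and diuretic studies.

Wilcoxon signed-rank and rank-sum tests use exact permutation nulls at
small sample sizes (the regime of 6-12 subjects this kind of study runs
at), where the normal approximation is unreliable and the attainable
p-values are strongly discrete.  Exact mode enumerates the full null —
sign assignments for the signed-rank test, group assignments for the
rank-sum test — and therefore handles ties without special cases.  Beyond
the exact cutoff the standard normal approximations with tie corrections
are used (Pratt's zero handling for the signed-rank test).

Two-sided p-values throughout; significance convention alpha = 0.05 with
Bonferroni adjustment for families of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .core import DataError

__all__ = [
    "StatResult",
    "LinearFit",
    "wilcoxon_signed_rank",
    "rank_sum",
    "kruskal_wallis",
    "bonferroni_adjust",
    "cov_percent",
    "linear_fit_r2",
    "max_percent_change",
]

EXACT_N_MAX = 12  # full enumeration cutoff for both exact tests


@dataclass
class StatResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p_value: float
    n: int
    adjusted: bool = False
    adjust_method: str | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DataError(f"p-value {self.p_value} outside [0, 1]")
        if self.n < 1:
            raise DataError("n must be >= 1")


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@lru_cache(maxsize=32)
def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign patterns as a (2^n, n) 0/1 matrix."""
    idx = np.arange(2 ** n, dtype=np.uint32)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(float)


def _two_sided_from_null(null: np.ndarray, observed: float) -> float:
    """Two-sided p by symmetry about the null mean: P(|T - mu| >= |t - mu|)."""
    mu = null.mean()
    return float(np.mean(np.abs(null - mu) >= abs(observed - mu) - 1e-12))


def wilcoxon_signed_rank(paired_a, paired_b, mode: str = "auto") -> StatResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Exact mode (default for n <= 12 non-zero differences after zero removal)
    enumerates all sign assignments of the |difference| ranks; ties are
    handled naturally by the enumeration.  Approximate mode uses the normal
    approximation with tie correction and Pratt's treatment of zero
    differences (zeros ranked, then excluded from the statistic).

    The statistic is W+ (sum of positive-difference ranks).  If every
    difference is zero the result is degenerate: statistic 0, p = 1, with a
    note flagging it.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("paired samples must be equal-length 1-D sequences")
    d = a - b
    nz = d != 0
    if not nz.any():
        return StatResult("wilcoxon_signed_rank", 0.0, 1.0, len(d),
                          note="all differences zero; degenerate")
    if mode not in ("auto", "exact", "approx"):
        raise DataError(f"unknown mode {mode!r}")

    n_nz = int(nz.sum())
    use_exact = mode == "exact" or (mode == "auto" and n_nz <= EXACT_N_MAX)

    if use_exact:
        # zeros dropped in exact mode
        dd = d[nz]
        if len(dd) < 3:
            raise DataError("need >= 3 non-zero differences")
        ranks = sps.rankdata(np.abs(dd))
        w_obs = float(ranks[dd > 0].sum())
        null = _sign_matrix(len(dd)) @ ranks
        p = _two_sided_from_null(null, w_obs)
        return StatResult("wilcoxon_signed_rank(exact)", w_obs, p, len(dd))

    # Pratt: rank |d| including zeros, drop zero ranks from the statistic
    if n_nz < 3:
        raise DataError("need >= 3 non-zero differences")
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    n_zero = n - n_nz
    mu = (n * (n + 1) - n_zero * (n_zero + 1)) / 4.0
    var = (n * (n + 1) * (2 * n + 1) - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24.0
    _, tie_counts = np.unique(ranks[d != 0], return_counts=True)
    var -= float((tie_counts ** 3 - tie_counts).sum()) / 48.0
    if var <= 0:
        return StatResult("wilcoxon_signed_rank(approx)", w_obs, 1.0, n_nz,
                          note="zero variance; degenerate")
    z = (w_obs - mu - 0.5 * np.sign(w_obs - mu)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return StatResult("wilcoxon_signed_rank(approx)", w_obs, p, n_nz)


@lru_cache(maxsize=32)
def _subset_index(n_total: int, n_a: int) -> np.ndarray:
    """All C(n_total, n_a) index subsets as an array of row indices."""
    return np.array(list(combinations(range(n_total), n_a)), dtype=np.intp)


def rank_sum(group_a, group_b, mode: str = "auto") -> StatResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test for two unpaired groups.

    Exact mode (default for combined n <= 12) enumerates every assignment
    of the pooled ranks to group A.  The statistic reported is U for group
    A; the p-value is computed on the rank-sum scale (equivalent, and tie
    safe).  Approximate mode is the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise DataError("both groups must be 1-D with >= 2 observations")
    if mode not in ("auto", "exact", "approx"):
        raise DataError(f"unknown mode {mode!r}")
    na, nb = len(a), len(b)
    n = na + nb
    ranks = sps.rankdata(np.concatenate([a, b]))
    r_obs = float(ranks[:na].sum())
    u_obs = r_obs - na * (na + 1) / 2.0

    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_N_MAX)
    if use_exact:
        combos = _subset_index(n, na)
        null = ranks[combos].sum(axis=1)
        p = _two_sided_from_null(null, r_obs)
        return StatResult("rank_sum(exact)", u_obs, p, n)

    mu = na * nb / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return StatResult("rank_sum(approx)", u_obs, 1.0, n,
                          note="zero variance; degenerate")
    z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return StatResult("rank_sum(approx)", u_obs, p, n)


def kruskal_wallis(groups) -> StatResult:
    """Kruskal-Wallis H test across >= 2 groups, tie-corrected.

    All-identical data is degenerate: H = 0, p = 1, flagged in ``note``.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise DataError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(gs)
    n = len(pooled)
    if np.all(pooled == pooled[0]):
        return StatResult("kruskal_wallis", 0.0, 1.0, n,
                          note="all observations identical; degenerate")
    ranks = sps.rankdata(pooled)
    h = 12.0 / (n * (n + 1)) * sum(
        r.sum() ** 2 / len(r) for r in np.split(ranks, np.cumsum([len(g) for g in gs])[:-1])
    ) - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float((tie_counts ** 3 - tie_counts).sum()) / (n ** 3 - n)
    h /= correction
    df = len(gs) - 1
    p = float(sps.chi2.sf(h, df))
    return StatResult("kruskal_wallis", float(h), p, n)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p); m defaults to len(p)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise DataError("m must be >= number of p-values")
    return np.minimum(1.0, m * p)


def cov_percent(values) -> float:
    """Coefficient of variation, percent: 100 * sample sd / mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise DataError("need >= 2 values for a CoV")
    mean = v.mean()
    if mean == 0:
        raise DataError("CoV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def linear_fit_r2(x, y) -> LinearFit:
    """OLS line fit; R^2 is the squared Pearson correlation, p from the
    slope's t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DataError("need equal-length 1-D x, y with n >= 3")
    if np.all(x == x[0]):
        raise DataError("x is constant; line fit undefined")
    res = sps.linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue ** 2),
                     p_value=float(res.pvalue), n=len(x))


def max_percent_change(values, baseline: float) -> float:
    """Largest |percent change| of a series relative to a baseline value."""
    v = np.asarray(values, dtype=float)
    if baseline == 0:
        raise DataError("baseline must be non-zero")
    return float(np.max(np.abs(v - baseline) / abs(baseline)) * 100.0)
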