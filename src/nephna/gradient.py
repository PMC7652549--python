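"""Corticomedullary gradient estimation from layer profiles.

The gradient is the signed slope of an unweighted OLS fit of layer mean
concentration (mmol/L) on layer mean depth (mm); positive values mean
concentration rising from cortex toward medulla.  A voxel-count-weighted
fit is available as an option.  For a dynamic (furosemide) study the
gradient is fitted per time point, and across subjects each post-baseline
time is compared against baseline with a paired signed-rank test under a
Bonferroni family correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataError
from .layers import Profile
from . import stats as st

__all__ = [
    "GradientResult",
    "fit_gradient",
    "dynamic_gradient_series",
    "first_significant_time",
]


@dataclass
class GradientResult:
    """Slope (mmol/L/mm), intercept (mmol/L) and R^2 of a layer profile fit."""

    slope: float
    intercept: float
    r_squared: float
    n_layers: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise DataError("gradient slope is not finite")
        if not 0.0 <= self.r_squared <= 1.0:
            raise DataError("R^2 outside [0, 1]")


def fit_gradient(profile: Profile, weighted: bool = False) -> GradientResult:
    """OLS fit of layer mean concentration on depth.

    A zero-variance (flat) profile gets slope 0 and, by convention,
    R^2 = 0 — this keeps dynamic result tables total.
    """
    depth = np.asarray(profile.depth_mm, dtype=float)
    y = np.asarray(profile.mean, dtype=float)
    if len(depth) < 3:
        raise DataError("need >= 3 layers to fit a gradient")
    w = np.asarray(profile.counts, dtype=float) if weighted else np.ones_like(y)
    wsum = w.sum()
    xbar = (w * depth).sum() / wsum
    ybar = (w * y).sum() / wsum
    sxx = (w * (depth - xbar) ** 2).sum()
    sxy = (w * (depth - xbar) * (y - ybar)).sum()
    syy = (w * (y - ybar) ** 2).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    if syy == 0:
        r2 = 0.0  # flat response: no variance to explain
    else:
        r2 = float(np.clip(sxy ** 2 / (sxx * syy), 0.0, 1.0))
    return GradientResult(slope=float(slope), intercept=float(intercept),
                          r_squared=r2, n_layers=len(depth))


def dynamic_gradient_series(profiles: list[Profile], times_min,
                            weighted: bool = False) -> list[GradientResult]:
    """Gradient fit at each time point of a dynamic study.

    Requires a baseline point at t = 0.
    """
    times = np.asarray(times_min, dtype=float)
    if len(profiles) != len(times):
        raise DataError("one profile per time point required")
    if len(times) == 0 or times[0] != 0.0:
        raise DataError("dynamic series must start with a baseline at t=0")
    return [fit_gradient(p, weighted=weighted) for p in profiles]


def first_significant_time(per_subject_values: np.ndarray, times_min,
                           alpha: float = 0.05,
                           adjust: str | None = "bonferroni") -> tuple[float | None, np.ndarray]:
    """First post-baseline time with a significant paired change vs baseline.

    ``per_subject_values`` is (n_subjects, n_times); column 0 is baseline.
    Each later column is compared to baseline with a two-sided Wilcoxon
    signed-rank test; with ``adjust="bonferroni"`` the p-values are
    multiplied by the number of post-baseline comparisons.  Note that with
    very few subjects the exact test's attainable p-values are discrete
    (floor 2/2^n), so the corrected series can be incapable of reaching
    ``alpha``; the uncorrected mode (``adjust=None``) is then the
    informative one.

    Returns (first significant time or None, adjusted p-values per
    post-baseline time).
    """
    vals = np.asarray(per_subject_values, dtype=float)
    times = np.asarray(times_min, dtype=float)
    if vals.ndim != 2 or vals.shape[1] != len(times):
        raise DataError("values must be (n_subjects, n_times)")
    if times[0] != 0.0:
        raise DataError("missing baseline at t=0")
    baseline = vals[:, 0]
    ps = np.array([st.wilcoxon_signed_rank(vals[:, j], baseline).p_value
                   for j in range(1, vals.shape[1])])
    if adjust == "bonferroni":
        ps = st.bonferroni_adjust(ps, m=len(ps))
    elif adjust is not None:
        raise DataError(f"unknown adjustment {adjust!r}")
    sig = np.nonzero(ps < alpha)[0]
    t_first = float(times[1:][sig[0]]) if sig.size else None
    return t_first, ps
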