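"""Inversion-recovery T1 fitting and steady-state saturation factors.

Sodium acquisitions run at short TR relative to tissue T1, so the
steady-state signal is saturated by a T1-dependent factor.  If the tissue
and the calibration phantoms relax at different rates, the phantom-based
concentration calibration is biased by the ratio of their saturation
factors; this module quantifies that ratio.

The IR signal model is the magnitude inversion-recovery curve

    S(TI) = | S0 * (1 - 2 * exp(-TI / T1)) |

fitted per voxel.  The magnitude (absolute-value) form is the default
because the inputs are magnitude images; a polarity-restored variant is
available for densely sampled TI series where the null point is bracketed.
The model assumes full recovery between inversions (TR >> TI recovery),
the standard IR simplification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import DataError, ImageVolume

__all__ = [
    "IRSeries",
    "T1Map",
    "fit_ir_t1",
    "null_point_t1",
    "saturation_factor",
    "saturation_bias",
]

log = logging.getLogger(__name__)

_LN2 = float(np.log(2.0))


@dataclass
class IRSeries:
    """An inversion-recovery series: one magnitude volume per TI (ms)."""

    tis: np.ndarray
    volumes: list[ImageVolume]

    def __post_init__(self) -> None:
        self.tis = np.asarray(self.tis, dtype=float)
        if self.tis.ndim != 1 or len(self.tis) < 3:
            raise DataError("need at least 3 inversion times for T1 fitting")
        if np.any(np.diff(self.tis) <= 0):
            raise DataError("inversion times must be strictly increasing")
        if np.any(self.tis <= 0):
            raise DataError("inversion times must be positive")
        if len(self.volumes) != len(self.tis):
            raise DataError("one volume per inversion time required")
        shp = self.volumes[0].shape
        if any(v.shape != shp for v in self.volumes):
            raise DataError("IR volumes must share a common grid")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.volumes[0].spacing

    def stack(self) -> np.ndarray:
        """(n_ti, *grid) array of the series."""
        return np.stack([v.data for v in self.volumes], axis=0)


@dataclass
class T1Map:
    """Per-voxel T1 (ms, NaN outside the fitted mask) and residual norm."""

    t1: np.ndarray
    residual: np.ndarray
    spacing: tuple[float, float, float]
    n_failed: int = 0


def _ir_magnitude(ti: np.ndarray, s0: float, t1: float) -> np.ndarray:
    return np.abs(s0 * (1.0 - 2.0 * np.exp(-ti / t1)))


def _ir_signed(ti: np.ndarray, s0: float, t1: float) -> np.ndarray:
    return s0 * (1.0 - 2.0 * np.exp(-ti / t1))


def null_point_t1(ti_null: float) -> float:
    """T1 implied by an observed signal null at ``ti_null``: T1 = TI/ln 2."""
    if ti_null <= 0:
        raise DataError("null-point TI must be positive")
    return ti_null / _LN2


def fit_ir_t1(series: IRSeries, mask: np.ndarray,
              polarity_restored: bool = False) -> T1Map:
    """Fit T1 voxelwise inside ``mask`` from an inversion-recovery series.

    Starting values come from the observed null point (the TI of minimum
    magnitude, T1_0 = TI_min/ln2) and the maximum magnitude (S0).  Voxels
    whose fit does not converge are set to NaN and counted.

    Parameters
    ----------
    series :
        IR magnitude volumes with their TIs (ms).
    mask :
        Boolean grid selecting the voxels to fit.
    polarity_restored :
        If True, flip the sign of samples before the estimated null and fit
        the signed recovery curve instead of its magnitude.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.volumes[0].shape:
        raise DataError("mask grid does not match the IR series")
    if not mask.any():
        raise DataError("empty mask")

    tis = series.tis
    sig = series.stack()[:, mask].T  # (n_vox, n_ti)
    t1 = np.full(mask.shape, np.nan)
    res = np.full(mask.shape, np.nan)
    t1_vals = np.full(sig.shape[0], np.nan)
    res_vals = np.full(sig.shape[0], np.nan)
    n_failed = 0

    for i, y in enumerate(sig):
        s0_0 = float(y.max())
        i_null = int(np.argmin(y))
        t1_0 = max(tis[i_null] / _LN2, 1e-3)
        try:
            if polarity_restored:
                # the true polarity boundary is on either side of the
                # magnitude minimum; fit both and keep the better one
                best = None
                for k in (i_null, i_null + 1):
                    y_fit = y.copy()
                    y_fit[:k] *= -1.0
                    try:
                        popt, _ = curve_fit(_ir_signed, tis, y_fit,
                                            p0=(s0_0, t1_0), maxfev=2000)
                    except (RuntimeError, ValueError):
                        continue
                    r = float(np.linalg.norm(y_fit - _ir_signed(tis, *popt)))
                    if best is None or r < best[1]:
                        best = (popt, r)
                if best is None:
                    raise RuntimeError("no polarity candidate converged")
                (s0_hat, t1_hat), resid = best
            else:
                popt, _ = curve_fit(_ir_magnitude, tis, y,
                                    p0=(s0_0, t1_0), maxfev=2000)
                s0_hat, t1_hat = popt
                resid = float(np.linalg.norm(y - _ir_magnitude(tis, *popt)))
            if not np.isfinite(t1_hat) or t1_hat <= 0:
                raise RuntimeError("non-physical T1")
            t1_vals[i] = t1_hat
            res_vals[i] = resid
        except (RuntimeError, ValueError):
            n_failed += 1

    t1[mask] = t1_vals
    res[mask] = res_vals
    if n_failed:
        log.warning("fit_ir_t1: %d/%d voxels did not converge (set to NaN)",
                    n_failed, sig.shape[0])
    return T1Map(t1=t1, residual=res, spacing=series.spacing, n_failed=n_failed)


def saturation_factor(t1: float, tr: float, flip_deg: float) -> float:
    """Spoiled steady-state signal factor f = (1-E) sin a / (1 - E cos a).

    ``E = exp(-TR/T1)``.  In the long-TR limit f -> sin(a); shorter TR or
    longer T1 saturates the signal (smaller f).

    Parameters
    ----------
    t1, tr : ms
    flip_deg : excitation flip angle, degrees, in (0, 90].
    """
    if t1 <= 0 or tr <= 0:
        raise DataError("t1 and tr must be positive")
    if not 0 < flip_deg <= 90:
        raise DataError("flip angle must be in (0, 90] degrees")
    a = np.deg2rad(flip_deg)
    e = np.exp(-tr / t1)
    return float((1.0 - e) * np.sin(a) / (1.0 - e * np.cos(a)))


def saturation_bias(t1_a: float, t1_b: float, tr: float, flip_deg: float) -> float:
    """Percent signal difference from T1 saturation between two compartments.

    Returns 100 * |f(t1_a) - f(t1_b)| / f(t1_b); e.g. tissue vs phantom.
    """
    fa = saturation_factor(t1_a, tr, flip_deg)
    fb = saturation_factor(t1_b, tr, flip_deg)
    return float(100.0 * abs(fa - fb) / fb)
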