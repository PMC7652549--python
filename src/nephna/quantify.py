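"""Signal-to-concentration conversion via phantom calibration.

Calibration phantoms of known sodium concentration imaged in the field of
view give an ordinary-least-squares line ``signal = slope * conc +
intercept``.  Before fitting, phantom region means are taken on the
transmit-B1-normalised signal so that the fitted slope is free of the
local B1 scale at the phantom positions.  The map is then

    conc = (signal - intercept) / (slope * b1_scale * f_tissue / f_phantom)

where ``f_tissue / f_phantom`` is the bulk T1-saturation ratio between
tissue and phantom material (a single scalar; the study treats saturation
as a bulk few-percent effect).  Negative calibrated values are clipped to
zero (physical constraint) and counted.  Receive-B1 correction is
deliberately not performed, mirroring the acquisition convention this
pipeline models; it is a known residual bias source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import CalibrationError, DataError, ImageVolume, RegionSummary

__all__ = [
    "CalibrationModel",
    "B1Map",
    "fit_calibration",
    "b1_map_double_angle",
    "apply_calibration",
    "region_mean",
    "phantom_signal_means",
]

log = logging.getLogger(__name__)


@dataclass
class CalibrationModel:
    """Fitted signal-vs-concentration line plus saturation factors."""

    slope: float                 # signal units per mmol/L
    intercept: float             # signal units
    f_tissue: float = 1.0        # steady-state saturation factors, (0, 1]
    f_phantom: float = 1.0
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    concs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    signals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(
                f"implausible calibration: non-positive slope {self.slope:g}")
        for name, f in (("f_tissue", self.f_tissue), ("f_phantom", self.f_phantom)):
            if not 0 < f <= 1:
                raise CalibrationError(f"{name} must be in (0, 1], got {f:g}")


@dataclass
class B1Map:
    """Relative transmit scale (actual/nominal flip), NaN where undefined."""

    scale: np.ndarray
    spacing: tuple[float, float, float]
    nominal_alpha_deg: float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.scale) & (self.scale > 0) & (self.scale < 2)


def fit_calibration(phantom_signals, phantom_concs,
                    fit_intercept: bool = True,
                    f_tissue: float = 1.0,
                    f_phantom: float = 1.0) -> CalibrationModel:
    """OLS line through (concentration, mean signal) phantom points.

    ``fit_intercept=True`` (default) absorbs the Rician noise floor into
    the intercept; ``False`` forces the line through the origin.
    """
    sig = np.asarray(phantom_signals, dtype=float)
    conc = np.asarray(phantom_concs, dtype=float)
    if sig.shape != conc.shape or sig.ndim != 1 or len(sig) < 2:
        raise DataError("need >= 2 paired phantom signal/concentration values")
    if np.all(conc == conc[0]):
        raise CalibrationError("degenerate calibration: all phantom "
                               "concentrations equal")
    if fit_intercept:
        A = np.column_stack([conc, np.ones_like(conc)])
        (slope, intercept), *_ = np.linalg.lstsq(A, sig, rcond=None)
    else:
        slope = float(conc @ sig / (conc @ conc))
        intercept = 0.0
    residuals = sig - (slope * conc + intercept)
    return CalibrationModel(slope=float(slope), intercept=float(intercept),
                            f_tissue=f_tissue, f_phantom=f_phantom,
                            residuals=residuals, concs=conc, signals=sig)


def b1_map_double_angle(vol_alpha: ImageVolume, vol_2alpha: ImageVolume,
                        nominal_alpha_deg: float) -> B1Map:
    """Transmit-B1 map from the double-angle method.

    With acquisitions at flip angles a and 2a, the actual flip is
    ``arccos(S_2a / (2 S_a))``; the B1 scale is actual/nominal.  Voxels
    with ``S_a = 0`` are undefined and set to NaN.
    """
    if vol_alpha.shape != vol_2alpha.shape:
        raise DataError("double-angle volumes must share a grid")
    if not 0 < nominal_alpha_deg < 90:
        raise DataError("nominal flip angle must be in (0, 90) degrees")
    s1 = vol_alpha.data
    s2 = vol_2alpha.data
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.clip(s2 / (2.0 * s1), -1.0, 1.0)
        actual = np.degrees(np.arccos(ratio))
    actual[s1 == 0] = np.nan
    return B1Map(scale=actual / nominal_alpha_deg, spacing=vol_alpha.spacing,
                 nominal_alpha_deg=nominal_alpha_deg)


def phantom_signal_means(signal: ImageVolume, phantom_masks,
                         b1: B1Map | None = None) -> np.ndarray:
    """Mean signal per phantom, B1-normalised voxelwise when a map is given."""
    data = signal.data
    if b1 is not None:
        with np.errstate(invalid="ignore"):
            data = data / b1.scale
    means = []
    for k, pm in enumerate(phantom_masks):
        vals = data[np.asarray(pm, dtype=bool)]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise DataError(f"phantom {k}: empty or fully invalid mask")
        means.append(vals.mean())
    return np.asarray(means)


def apply_calibration(signal: ImageVolume, model: CalibrationModel,
                      b1: B1Map | None = None,
                      tissue_mask: np.ndarray | None = None) -> ImageVolume:
    """Convert a signal volume to a concentration map (mmol/L).

    Negative calibrated values are clipped to 0 and the clip count logged.
    Raises if the B1 scale is non-positive anywhere inside ``tissue_mask``.
    """
    denom_scalar = model.slope * (model.f_tissue / model.f_phantom)
    if b1 is None:
        b1_scale = np.ones(signal.shape)
    else:
        if b1.scale.shape != signal.shape:
            raise DataError("B1 map grid does not match the signal grid")
        b1_scale = b1.scale
        if tissue_mask is not None:
            bad = ~(b1_scale[np.asarray(tissue_mask, dtype=bool)] > 0)
            if bad.any():
                raise DataError(f"B1 scale <= 0 at {int(bad.sum())} voxels "
                                "inside the tissue mask")
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = (signal.data - model.intercept) / (denom_scalar * b1_scale)
    n_neg = int(np.sum(conc < 0))
    if n_neg:
        log.info("apply_calibration: clipped %d negative voxels to 0", n_neg)
    conc = np.clip(conc, 0.0, None)
    return signal.like(conc, modality="concentration")


def region_mean(conc: ImageVolume, mask: np.ndarray, name: str = "roi") -> RegionSummary:
    """Arithmetic mean and sample SD of a map over an ROI mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != conc.shape:
        raise DataError("mask grid does not match the map")
    vals = conc.data[mask]
    if vals.size == 0:
        raise DataError(f"region {name!r}: empty mask")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return RegionSummary(region=name, mean=float(vals.mean()), sd=sd,
                         n_voxels=int(vals.size))
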