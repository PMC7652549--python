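"""Synthetic renal sodium-MRI data generator.

Emulates the statistical structure of a quantitative renal sodium imaging
study so that every downstream stage (calibration, layer segmentation,
gradient estimation, reproducibility statistics) can be exercised without
scanner data:

* a two-compartment kidney — nested ellipsoids, outer shell = cortex,
  inner core = medulla — with either a step or a linear corticomedullary
  concentration profile;
* agar-style calibration phantoms of known concentration placed in the
  field of view outside the kidney;
* signal formation: signal = slope_true x concentration x saturation
  factor (per-compartment, from T1/TR/flip) x smooth multiplicative
  transmit-B1 field, plus Rician magnitude noise;
* a double-angle acquisition pair for transmit-B1 mapping;
* cohorts with inter-subject variability on regional concentrations;
* furosemide washout dynamics (exponential medullary decay, slow cortical
  drift, fixed anatomy) and flat serum electrolyte panels;
* inversion-recovery series for T1 mapping.

With the linear profile, truth concentration is an affine function of the
boundary distance (depth), anchored so that the *mean* over the cortex
mask equals ``cortex_conc`` and the mean over the medulla mask equals
``medulla_conc`` — regional truth means therefore match the configured
values exactly, and the implied true gradient slope is
``(medulla_conc - cortex_conc) / depth_span``.

All randomness descends from integer seeds through ``numpy`` seed
sequences; a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import yaml

from .core import ConfigError, DataError, GeometryError, ImageVolume, write_labels, write_nifti
from .relaxometry import IRSeries, saturation_factor

__all__ = [
    "KidneyGeometry",
    "SubjectConfig",
    "SyntheticSubject",
    "WashoutConfig",
    "SerumPanel",
    "DynamicStudyInputs",
    "human_config",
    "porcine_config",
    "generate_subject",
    "generate_cohort",
    "generate_dynamic_study",
    "generate_ir_series",
    "simulate_serum",
    "write_subject",
    "SERUM_BASELINE",
]

# physiologic serum baselines, mmol/L (sodium per the study; potassium and
# chloride at textbook values — see the methods note on the printed labels)
SERUM_BASELINE = {"sodium": 139.0, "potassium": 4.0, "chloride": 103.0}


@dataclass(frozen=True)
class KidneyGeometry:
    """Nested-ellipsoid kidney: outer = whole kidney, inner = medulla."""

    outer_semi_axes_mm: tuple[float, float, float]
    inner_semi_axes_mm: tuple[float, float, float]
    center_frac: tuple[float, float, float] = (0.40, 0.5, 0.5)

    @classmethod
    def from_medulla_fraction(cls, outer_semi_axes_mm, medulla_fraction: float,
                              center_frac=(0.40, 0.5, 0.5)) -> "KidneyGeometry":
        """Inner core scaled isotropically to a medullary volume fraction."""
        if not 0 < medulla_fraction < 1:
            raise ConfigError("medulla_fraction must be in (0, 1)")
        k = medulla_fraction ** (1.0 / 3.0)
        inner = tuple(k * s for s in outer_semi_axes_mm)
        return cls(tuple(outer_semi_axes_mm), inner, tuple(center_frac))

    def validate(self) -> None:
        if any(i >= o for i, o in zip(self.inner_semi_axes_mm,
                                      self.outer_semi_axes_mm)):
            raise ConfigError("medullary core must lie strictly inside the kidney")
        if any(s <= 0 for s in self.outer_semi_axes_mm + self.inner_semi_axes_mm):
            raise ConfigError("ellipsoid semi-axes must be positive")


@dataclass
class SubjectConfig:
    """Everything needed to synthesise one subject.

    Concentrations in mmol/L, times in ms (T1, TR) except where noted,
    spatial sizes in mm, noise in raw signal units.
    """

    grid_shape: tuple[int, int, int] = (96, 64, 48)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    kidney_geometry: KidneyGeometry = field(
        default_factory=lambda: KidneyGeometry.from_medulla_fraction((45.0, 28.0, 22.0), 0.33))
    cortex_conc: float = 72.0
    medulla_conc: float = 136.0
    profile_kind: str = "linear"          # or "step"
    cortex_medulla_depth_span: float | None = None  # mm; None -> from geometry
    phantom_concs: tuple[float, ...] = (50.0, 100.0, 154.0)
    phantom_radius_mm: float = 8.0
    t1_tissue: float = 26.0
    t1_phantom: float = 22.0
    tr: float = 10.0
    flip_deg: float = 25.0
    calib_slope_true: float = 1.0
    b1_amplitude: float = 0.10            # peak deviation of the B1 field from 1
    noise_sigma: float = 1.7              # Rician scale; cortical SNR ~ 15 at defaults
    intersubject_cov: float = 0.05
    apply_saturation: bool = True
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ConfigError("grid_shape must be 3 positive integers")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigError("spacing must be positive on all axes")
        self.kidney_geometry.validate()
        if self.profile_kind not in ("step", "linear"):
            raise ConfigError(f"unknown profile_kind {self.profile_kind!r}")
        if self.cortex_medulla_depth_span is not None and self.cortex_medulla_depth_span <= 0:
            raise ConfigError("cortex_medulla_depth_span must be positive")
        if len(self.phantom_concs) < 1 or any(c <= 0 for c in self.phantom_concs):
            raise ConfigError("phantom concentrations must be positive")
        if len(set(self.phantom_concs)) != len(self.phantom_concs):
            raise ConfigError("phantom concentrations must be distinct")
        if not 0 <= self.intersubject_cov < 1:
            raise ConfigError("intersubject_cov must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.cortex_conc <= 0 or self.medulla_conc <= 0:
            raise ConfigError("compartment concentrations must be positive")
        if self.t1_tissue <= 0 or self.t1_phantom <= 0 or self.tr <= 0:
            raise ConfigError("T1 and TR must be positive")


def human_config(**overrides) -> SubjectConfig:
    """Default in-vivo human configuration (12-layer study)."""
    cfg = SubjectConfig(**overrides) if overrides else SubjectConfig()
    cfg.validate()
    return cfg


def porcine_config(**overrides) -> SubjectConfig:
    """Default porcine configuration (7-layer dynamic study).

    Geometry is calibrated so the cortex-to-medulla mean-depth span is
    about 14 mm, putting the default 53->92 mmol/L linear profile near a
    2.8 mmol/L/mm corticomedullary slope.
    """
    defaults = dict(
        grid_shape=(96, 72, 60),
        spacing=(1.5, 1.5, 1.5),
        kidney_geometry=KidneyGeometry.from_medulla_fraction((55.0, 38.0, 32.0), 0.18),
        cortex_conc=53.0,
        medulla_conc=92.0,
    )
    defaults.update(overrides)
    cfg = SubjectConfig(**defaults)
    cfg.validate()
    return cfg


@dataclass
class SyntheticSubject:
    """One synthesised subject: truth, signal, masks and B1 ground truth."""

    truth_conc: ImageVolume
    signal: ImageVolume
    kidney_mask: np.ndarray
    cortex_mask: np.ndarray
    medulla_mask: np.ndarray
    phantom_masks: list[np.ndarray]
    b1_true: ImageVolume
    b1_vol_alpha: ImageVolume
    b1_vol_2alpha: ImageVolume
    depth_span_mm: float
    true_slope: float            # mmol/L/mm implied by the linear profile
    config: SubjectConfig
    seed: int

    @property
    def label_volume(self) -> np.ndarray:
        """0 background, 1 cortex, 2 medulla, 10+k phantom k."""
        lab = np.zeros(self.kidney_mask.shape, dtype=np.int16)
        lab[self.cortex_mask] = 1
        lab[self.medulla_mask] = 2
        for k, pm in enumerate(self.phantom_masks):
            lab[pm] = 10 + k
        return lab


@dataclass
class WashoutConfig:
    """Exponential medullary washout after a furosemide bolus.

    medulla(t) = baseline - (baseline - plateau) * (1 - exp(-t/tau));
    the cortex drifts linearly by ``cortex_drift`` mmol/L per 30 min.
    ``cortex_drift_sd`` is the animal-to-animal SD of that drift: the
    cortical response to the diuretic varies between animals (unlike the
    consistent medullary washout), which is what keeps the cortical
    pre/post comparison non-significant at small n.
    """

    baseline_medulla: float = 92.0
    plateau_medulla: float = 69.0
    tau_min: float = 8.0
    cortex_drift: float = 4.0
    cortex_drift_sd: float = 5.0
    times_min: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

    def validate(self) -> None:
        if self.tau_min <= 0:
            raise ConfigError("tau must be positive")
        t = np.asarray(self.times_min, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ConfigError("times must be ascending and start at 0")

    def medulla_at(self, t: float) -> float:
        return self.baseline_medulla - (self.baseline_medulla - self.plateau_medulla) \
            * (1.0 - np.exp(-t / self.tau_min))


@dataclass
class SerumPanel:
    """Serum electrolyte series (mmol/L) on a common time grid (min)."""

    times_min: np.ndarray
    analytes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.analytes = {k: np.asarray(v, dtype=float) for k, v in self.analytes.items()}
        for name, v in self.analytes.items():
            if v.shape != self.times_min.shape:
                raise DataError(f"serum analyte {name!r} length mismatch")
            if np.any(v <= 0):
                raise DataError(f"serum analyte {name!r} has non-positive values")


@dataclass
class DynamicStudyInputs:
    """One synthetic subject per time point, on fixed anatomy."""

    times_min: np.ndarray
    subjects: list[SyntheticSubject]
    washout: WashoutConfig


# ---------------------------------------------------------------------------
# geometry helpers

def _coords_mm(shape, spacing):
    idx = np.indices(shape).astype(float)
    # voxel-centre coordinates
    return [(idx[i] + 0.5) * spacing[i] for i in range(3)]


def _ellipsoid(coords, center, semi):
    r2 = sum(((coords[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return r2 <= 1.0


def _check_fits(center, semi, fov, what: str) -> None:
    axes = "xyz"
    for i in range(3):
        if center[i] - semi[i] < 0 or center[i] + semi[i] > fov[i]:
            raise GeometryError(
                f"{what} overflows the grid along axis {axes[i]!r}: "
                f"extent [{center[i] - semi[i]:.1f}, {center[i] + semi[i]:.1f}] mm "
                f"vs FOV [0, {fov[i]:.1f}] mm")


def _phantom_centers(cfg: SubjectConfig, fov, kidney_center, kidney_semi):
    """Spread phantom spheres along y on the +x side of the kidney."""
    n = len(cfg.phantom_concs)
    r = cfg.phantom_radius_mm
    x = kidney_center[0] + kidney_semi[0] + 2.0 * r
    z = fov[2] / 2.0
    ys = np.linspace(r * 1.5, fov[1] - r * 1.5, n) if n > 1 else [fov[1] / 2.0]
    return [(x, float(y), z) for y in ys]


def _b1_field(shape, spacing, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order polynomial multiplicative field, 1 +- amplitude."""
    if amplitude == 0:
        return np.ones(shape)
    coords = _coords_mm(shape, spacing)
    fov = [n * s for n, s in zip(shape, spacing)]
    u = [2.0 * c / f - 1.0 for c, f in zip(coords, fov)]  # in [-1, 1]
    c_lin = rng.uniform(-1, 1, size=3)
    c_quad = rng.uniform(-1, 1, size=(3, 3))
    c_quad = (c_quad + c_quad.T) / 2.0
    p = np.zeros(shape)
    for i in range(3):
        p += c_lin[i] * u[i]
        for j in range(3):
            p += c_quad[i, j] * u[i] * u[j]
    peak = np.max(np.abs(p))
    if peak > 0:
        p *= amplitude / peak
    return 1.0 + p


def _rician(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return clean.copy()
    n1 = rng.normal(0.0, sigma, size=clean.shape)
    n2 = rng.normal(0.0, sigma, size=clean.shape)
    return np.sqrt((clean + n1) ** 2 + n2 ** 2)


def _subseed(seed: int, *key: int) -> int:
    """Deterministic derived seed below 2^31."""
    return int(np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# subject generation

def _build_anatomy(cfg: SubjectConfig):
    """Masks, depth map and profile anchors shared across time points."""
    from .layers import depth_map  # local import to avoid cycles at import time

    shape = tuple(int(n) for n in cfg.grid_shape)
    spacing = tuple(float(s) for s in cfg.spacing)
    fov = [n * s for n, s in zip(shape, spacing)]
    geo = cfg.kidney_geometry
    center = tuple(f * c for f, c in zip(fov, geo.center_frac))
    _check_fits(center, geo.outer_semi_axes_mm, fov, "kidney")

    coords = _coords_mm(shape, spacing)
    kidney = _ellipsoid(coords, center, geo.outer_semi_axes_mm)
    medulla = _ellipsoid(coords, center, geo.inner_semi_axes_mm)
    cortex = kidney & ~medulla

    phantom_masks = []
    for pc, pcenter in zip(cfg.phantom_concs,
                           _phantom_centers(cfg, fov, center, geo.outer_semi_axes_mm)):
        _check_fits(pcenter, (cfg.phantom_radius_mm,) * 3, fov,
                    f"phantom ({pc:g} mmol/L)")
        pm = _ellipsoid(coords, pcenter, (cfg.phantom_radius_mm,) * 3)
        if (pm & kidney).any():
            raise GeometryError("phantom overlaps the kidney")
        phantom_masks.append(pm)

    depth = depth_map(kidney, spacing)
    d_ctx = float(depth[cortex].mean())
    d_med = float(depth[medulla].mean())
    return shape, spacing, kidney, cortex, medulla, phantom_masks, depth, d_ctx, d_med


def _truth_map(cfg: SubjectConfig, anatomy) -> tuple[np.ndarray, float, float]:
    shape, spacing, kidney, cortex, medulla, phantom_masks, depth, d_ctx, d_med = anatomy
    truth = np.zeros(shape)
    if cfg.profile_kind == "step":
        truth[cortex] = cfg.cortex_conc
        truth[medulla] = cfg.medulla_conc
        span = cfg.cortex_medulla_depth_span or (d_med - d_ctx)
        slope = (cfg.medulla_conc - cfg.cortex_conc) / span
    else:
        span = cfg.cortex_medulla_depth_span or (d_med - d_ctx)
        slope = (cfg.medulla_conc - cfg.cortex_conc) / span
        truth[kidney] = cfg.cortex_conc + slope * (depth[kidney] - d_ctx)
        if truth[kidney].min() < 0:
            raise ConfigError("linear profile goes negative at the kidney surface; "
                              "reduce the slope or raise cortex_conc")
    for pc, pm in zip(cfg.phantom_concs, phantom_masks):
        truth[pm] = pc
    return truth, span, slope


def _generate(cfg: SubjectConfig, seed: int, b1: np.ndarray | None,
              noise_rng: np.random.Generator, anatomy=None) -> SyntheticSubject:
    cfg.validate()
    if anatomy is None:
        anatomy = _build_anatomy(cfg)
    shape, spacing, kidney, cortex, medulla, phantom_masks, depth, d_ctx, d_med = anatomy
    truth, span, slope = _truth_map(cfg, anatomy)

    if b1 is None:
        b1 = _b1_field(shape, spacing, cfg.b1_amplitude,
                       np.random.default_rng(_subseed(seed, 101)))

    sat = np.ones(shape)
    if cfg.apply_saturation:
        sat[kidney] = saturation_factor(cfg.t1_tissue, cfg.tr, cfg.flip_deg)
        for pm in phantom_masks:
            sat[pm] = saturation_factor(cfg.t1_phantom, cfg.tr, cfg.flip_deg)

    clean = cfg.calib_slope_true * truth * sat * b1
    noisy = _rician(clean, cfg.noise_sigma, noise_rng)

    # noiseless double-angle proton-style pair for transmit-B1 mapping
    alpha = np.deg2rad(cfg.flip_deg)
    amp = 100.0
    vol_a = amp * np.sin(b1 * alpha)
    vol_2a = amp * np.sin(2.0 * b1 * alpha)

    return SyntheticSubject(
        truth_conc=ImageVolume(truth, spacing, "concentration"),
        signal=ImageVolume(noisy, spacing, "na_signal"),
        kidney_mask=kidney, cortex_mask=cortex, medulla_mask=medulla,
        phantom_masks=phantom_masks,
        b1_true=ImageVolume(b1, spacing, "b1_scale"),
        b1_vol_alpha=ImageVolume(vol_a, spacing, "b1_alpha"),
        b1_vol_2alpha=ImageVolume(vol_2a, spacing, "b1_2alpha"),
        depth_span_mm=span, true_slope=slope, config=cfg, seed=seed)


def generate_subject(config: SubjectConfig, seed: int | None = None) -> SyntheticSubject:
    """Generate one synthetic subject; deterministic for a fixed seed."""
    seed = config.seed if seed is None else int(seed)
    noise_rng = np.random.default_rng(_subseed(seed, 202))
    return _generate(config, seed, None, noise_rng)


def generate_cohort(n_per_site: int, site_configs: list[SubjectConfig],
                    seed: int) -> list[list[SyntheticSubject]]:
    """Generate ``n_per_site`` subjects per site configuration.

    Per-subject cortical and medullary concentrations are drawn around the
    site means with relative SD ``intersubject_cov``; each subject is
    reproducible from (site index, subject index, seed) alone.
    """
    if n_per_site < 0:
        raise ConfigError("n_per_site must be >= 0")
    cohort: list[list[SyntheticSubject]] = []
    for s, cfg in enumerate(site_configs):
        cfg.validate()
        site_subjects = []
        for i in range(n_per_site):
            sub_seed = _subseed(seed, s, i)
            draw_rng = np.random.default_rng(_subseed(sub_seed, 303))
            cov = cfg.intersubject_cov
            ctx = float(draw_rng.normal(cfg.cortex_conc, cov * cfg.cortex_conc))
            med = float(draw_rng.normal(cfg.medulla_conc, cov * cfg.medulla_conc))
            if ctx <= 0 or med <= 0:
                raise DataError("drawn subject concentration non-positive; "
                                "intersubject_cov too large")
            sub_cfg = replace(cfg, cortex_conc=ctx, medulla_conc=med, seed=sub_seed)
            site_subjects.append(generate_subject(sub_cfg, sub_seed))
        cohort.append(site_subjects)
    return cohort


def generate_dynamic_study(config: SubjectConfig, washout: WashoutConfig,
                           seed: int) -> DynamicStudyInputs:
    """Furosemide time series: same anatomy and B1, evolving concentrations.

    Medullary truth follows the exponential washout; the cortex drifts
    linearly.  Noise is fresh at each time point.
    """
    config.validate()
    washout.validate()
    times = np.asarray(washout.times_min, dtype=float)
    anatomy = _build_anatomy(config)
    shape, spacing = anatomy[0], anatomy[1]
    b1 = _b1_field(shape, spacing, config.b1_amplitude,
                   np.random.default_rng(_subseed(seed, 101)))
    subjects = []
    for j, t in enumerate(times):
        med_t = float(washout.medulla_at(t))
        ctx_t = float(config.cortex_conc + washout.cortex_drift * t / 30.0)
        if med_t <= 0 or ctx_t <= 0:
            raise ConfigError(f"washout gives non-positive concentration at t={t:g} min")
        cfg_t = replace(config, medulla_conc=med_t, cortex_conc=ctx_t)
        noise_rng = np.random.default_rng(_subseed(seed, 404, j))
        subjects.append(_generate(cfg_t, seed, b1, noise_rng, anatomy=anatomy))
    return DynamicStudyInputs(times_min=times, subjects=subjects, washout=washout)


def generate_ir_series(config: SubjectConfig, tis, seed: int) -> IRSeries:
    """Inversion-recovery magnitude series with per-compartment T1."""
    config.validate()
    tis = np.asarray(tis, dtype=float)
    if len(tis) < 3 or np.any(tis <= 0):
        raise ConfigError("need >= 3 positive inversion times")
    anatomy = _build_anatomy(config)
    shape, spacing = anatomy[0], anatomy[1]
    kidney, phantom_masks = anatomy[2], anatomy[5]
    truth, _, _ = _truth_map(config, anatomy)

    t1 = np.full(shape, np.inf)   # background: no signal, T1 irrelevant
    t1[kidney] = config.t1_tissue
    for pm in phantom_masks:
        t1[pm] = config.t1_phantom
    s0 = config.calib_slope_true * truth

    vols = []
    for j, ti in enumerate(np.sort(tis)):
        clean = np.abs(s0 * (1.0 - 2.0 * np.exp(-ti / t1)))
        rng = np.random.default_rng(_subseed(seed, 505, j))
        vols.append(ImageVolume(_rician(clean, config.noise_sigma, rng),
                                spacing, "ir_magnitude"))
    return IRSeries(tis=np.sort(tis), volumes=vols)


def simulate_serum(baseline: dict[str, float] | None = None,
                   noise_cv: float = 0.015,
                   times=(0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
                   seed: int = 0) -> SerumPanel:
    """Flat serum electrolyte series with multiplicative measurement noise.

    Each analyte stays at its baseline; the serum seed stream is
    independent of the imaging streams.
    """
    if noise_cv < 0:
        raise ConfigError("noise_cv must be >= 0")
    baseline = dict(SERUM_BASELINE if baseline is None else baseline)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(_subseed(seed, 606))
    analytes = {}
    for name, base in baseline.items():
        if base <= 0:
            raise ConfigError(f"serum baseline {name!r} must be positive")
        noise = rng.normal(1.0, noise_cv, size=times.shape) if noise_cv > 0 else np.ones_like(times)
        analytes[name] = base * noise
    return SerumPanel(times_min=times, analytes=analytes)


# ---------------------------------------------------------------------------
# file output

def write_subject(subject: SyntheticSubject, out_dir: str | Path) -> Path:
    """Write signal, truth, labels and B1 volumes plus a YAML sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_nifti(subject.signal, out / "signal.nii.gz")
    write_nifti(subject.truth_conc, out / "truth_conc.nii.gz")
    write_nifti(subject.b1_vol_alpha, out / "b1_alpha.nii.gz")
    write_nifti(subject.b1_vol_2alpha, out / "b1_2alpha.nii.gz")
    write_labels(subject.label_volume, subject.signal.spacing, out / "labels.nii.gz")
    cfg = asdict(subject.config)
    cfg["kidney_geometry"] = asdict(subject.config.kidney_geometry)
    sidecar = {"config": _yaml_safe(cfg), "seed": int(subject.seed),
               "depth_span_mm": float(subject.depth_span_mm),
               "true_slope_mmol_l_mm": float(subject.true_slope)}
    (out / "subject.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return out


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
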