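# Methods

This note documents the models implemented in `nephna`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions. Nothing here states an empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Signal model and calibration

A magnitude sodium image is modelled voxelwise as

    S = s · C · f(T1; TR, α) · B1 + Rician(σ)

where `C` is tissue sodium concentration (mmol/L), `s` the scanner gain
(signal units per mmol/L), `f` the spoiled steady-state saturation factor

    f = (1 − E) sin α / (1 − E cos α),   E = e^(−TR/T1),

`B1` a smooth multiplicative transmit-field scale, and the noise is
Rician (Rayleigh at zero signal, ≈ Gaussian with sd σ at SNR > 3).

Calibration inverts this chain. Phantom ROI means are taken on the
B1-normalised signal (so the fitted slope is free of the local B1 scale
at the phantom positions), an OLS line `signal = slope·conc + intercept`
is fitted through the phantom points, and the map is

    C = (S − intercept) / (slope · B1 · f_tissue/f_phantom).

Choices worth noting:

- **Fitted intercept (default).** The Rician noise floor biases phantom
  means upward by ≈ σ²/2S; a free intercept absorbs the common part of
  that bias. A zero-intercept mode exists for noiseless or high-SNR use.
- **Bulk saturation ratio.** Tissue (T1 ≈ 26 ms) and agar phantom
  (T1 ≈ 22 ms) saturation differ by a few percent at short TR; the
  correction is applied as one scalar ratio `f_tissue/f_phantom`, not
  voxelwise, because compartmental T1 differences within the kidney are
  small against the noise. `saturation_bias()` quantifies the effect for
  arbitrary TR/flip; it grows quickly as TR shrinks.
- **Transmit B1 by the double-angle method**: actual flip =
  arccos(S₂α/2Sα), scale = actual/nominal; voxels with Sα = 0 are NaN.
  **Receive-B1 correction is deliberately not performed** — this mirrors
  the acquisition convention the pipeline models and is a known residual
  bias source.
- Negative calibrated voxels (background noise minus intercept) are
  clipped to 0 and counted; concentrations are physical quantities.

## Concentric layers and the corticomedullary gradient

The kidney mask is partitioned into N shells by the Euclidean distance of
each in-mask voxel to the nearest outside voxel centre, computed in mm
with anisotropic spacing (`scipy.ndimage.distance_transform_edt`).
Distances are binned into N equal-width, half-open [lo, hi) bins between
0 and the in-mask maximum; the deepest voxel joins layer N (ties break
inward). Equal-count (quantile) binning is available as an option.
Interior holes are filled before the transform and logged. The defaults
are 12 layers for human kidneys and 7 for the smaller porcine kidney.

The depth coordinate of a layer is its **mean boundary distance in mm**,
not the bin midpoint — robust to irregular shapes, and it makes the layer
means of any affine-in-depth concentration field exactly collinear.

The gradient is the slope of an unweighted OLS fit of layer mean
concentration on layer depth (mmol·L⁻¹·mm⁻¹; positive = rising toward
the medulla). A voxel-count-weighted fit is available. For a flat
(zero-variance) profile R² is defined as 0 rather than NaN so dynamic
result tables stay total.

## T1 relaxometry

Inversion-recovery series are fitted per voxel with the magnitude model
|S₀(1 − 2e^(−TI/T1))| (inputs are magnitude images; full recovery
between inversions is assumed, the standard IR simplification). Starting
values come from the observed null point (T1₀ = TI_min/ln 2) and the
maximum magnitude. Non-converged voxels are NaN and counted. A
polarity-restored variant fits the signed curve after testing both
candidate polarity boundaries around the magnitude minimum; it is
preferable only when the TI grid brackets the null point densely.

## The synthetic generator

The generator produces the statistical structure the analysis assumes,
not anatomical realism:

- **Geometry**: nested ellipsoids — outer = whole kidney, inner core =
  medulla, shell = cortex — plus spherical phantoms placed outside the
  organ. Human default: outer semi-axes (45, 28, 22) mm with a 0.33
  medullary volume fraction. Porcine default: (55, 38, 32) mm with a
  0.18 fraction; this porcine geometry is a deliberate calibration of
  the generator so that the cortex-to-medulla mean-depth span is ≈14 mm
  and the default 53→92 mmol/L profile implies a slope near
  2.8 mmol·L⁻¹·mm⁻¹ — the shape parameters are not measurements.
- **Truth profile**: with `profile_kind="linear"` (default, matching the
  observed linearity of depth profiles) concentration is affine in
  boundary depth, anchored so that the mean over the cortex mask equals
  `cortex_conc` and the mean over the medulla mask equals
  `medulla_conc`. Regional truth means therefore equal the configured
  values exactly, and the implied slope is (medulla − cortex)/span with
  span = difference of the regional mean depths (an explicit
  `cortex_medulla_depth_span` overrides the denominator). A step profile
  is kept for oracle tests.
- **Defaults** (human): cortex 72, medulla 136 mmol/L; phantoms 50, 100,
  154 mmol/L (saline at physiological strength as the top standard);
  T1 tissue 26 ms, phantom 22 ms; TR 10 ms, flip 25°; unit gain;
  B1 amplitude ±10% (seeded low-order polynomial field); Rician σ = 1.7
  signal units, giving cortical SNR ≈ 15 after saturation;
  inter-subject CoV 5% on regional concentrations only (geometry is
  fixed — this isolates the quantity under test). TR and flip are
  free parameters of the saturation model rather than fixed study
  constants; the defaults make the correction well-posed and a few
  percent in size.
- **Cohorts**: per-subject cortical/medullary concentrations are drawn
  around site means with relative SD = `intersubject_cov`; each subject
  is reproducible from (site, index, seed) alone. Site defaults follow
  the two-site study design: medullary means 137/133, cortical 72/70
  mmol/L, six volunteers per site.
- **Furosemide dynamics**: medullary truth follows
  m(t) = baseline − (baseline − plateau)(1 − e^(−t/τ)) on fixed anatomy
  and B1, fresh noise per time point. Defaults 92 → 69 mmol/L over
  0–30 min at 5-min intervals; τ = 8 min is a generator choice (only the
  endpoints are constrained by the emulated physiology) that puts
  m(30 min) ≈ 69.5 mmol/L with a clear intermediate transition. The
  cortical drift is +4 mmol/L per 30 min **with an animal-to-animal SD
  of 5 mmol/L**: the cortical response to the diuretic is variable
  between animals (SD taken equal to the printed regional SD), which is
  what keeps the cortical and whole-kidney pre/post comparisons
  non-significant at n = 6 while the consistent medullary washout is
  significant.
- **Serum**: analytes stay at baseline with multiplicative noise
  (CV 1.5%), independent of the imaging seed stream. Baselines are
  sodium 139, potassium 4.0, chloride 103 mmol/L — note that published
  serum tables in this literature sometimes carry transposed
  potassium/chloride labels; the generator uses physiologic values and
  does not reproduce label errors.

**What passing tests do not show**: the generator has no k-space or
trajectory simulation, no partial-volume mixing at compartment borders,
no respiratory motion, no receive-field inhomogeneity, no anatomical
lobulation of the medulla. Pipeline accuracy on this data therefore
demonstrates correctness of the analysis chain, not scanner-level
validity.

## Statistics

- Wilcoxon signed-rank and rank-sum tests use **exact permutation nulls**
  up to 12 (non-zero) observations: all 2ⁿ sign assignments of the
  |difference| ranks, respectively all C(n, n_a) group assignments of the
  pooled ranks. Enumeration handles ties without special cases; two-sided
  p-values are computed symmetrically about the null mean,
  P(|T − μ| ≥ |t − μ|). Beyond the cutoff, tie-corrected normal
  approximations with continuity correction are used (Pratt's zero
  handling for the signed-rank test; zeros are dropped in exact mode).
- Kruskal–Wallis uses the tie-corrected H with a χ² reference;
  all-identical input is degenerate (H = 0, p = 1, flagged).
- Bonferroni: p_adj = min(1, m·p). CoV = 100·sd/mean (sample sd).
- Significance α = 0.05 throughout, two-sided.
- **Family conventions in the studies**: intersite comparisons default to
  the unpaired rank-sum test (sites enrol different subjects; a paired
  "signed_rank" mode exists for strict pairing by index). Between-ROI
  comparisons are gated by Kruskal–Wallis and Bonferroni-corrected over
  the three ROI pairs. In the dynamic study, single pre-vs-post ROI
  comparisons are uncorrected (one comparison per family), while the
  gradient time course is Bonferroni-corrected over the post-baseline
  time points.
- **Discreteness caveat**: with six animals the exact signed-rank test's
  smallest two-sided p is 2/2⁶ = 0.03125, so a Bonferroni correction over
  six time points can never reach 0.05. The dynamic report therefore
  carries both the corrected first-significant time (which may be
  undefined for this structural reason) and the uncorrected one.

## Pipeline and reproducibility

All randomness descends from one root seed through named
`numpy.random.SeedSequence` substreams (subjects, B1, noise, serum), so
modules can be re-run independently and a fixed seed gives bit-identical
volumes and byte-identical `report.json` (reports carry a config hash and
package version, no timestamps). Study configuration is one YAML document
with a `study:` discriminator; unknown keys are rejected by name. CLI
exit codes: 0 success, 2 config error, 3 data error.

Problem sizes: the default human grid is 96×64×48 voxels at 1.5 mm
(FOV 144×96×72 mm) and the porcine grid 96×72×60 at 1.5 mm — fine enough
that 12 (respectively 7) equal-width layers are all populated, and small
enough that a full two-site study runs in seconds on one core.

## Known limitations

- Calibration accuracy inherits the phantom placement: B1 normalisation
  at the phantoms is exact here because the double-angle pair is
  noiseless; with noisy B1 acquisitions the slope picks up additional
  variance not modelled in the tests.
- The bulk saturation correction ignores within-kidney T1 heterogeneity.
- Layer depth uses the outer boundary only; organs with true interior
  cavities would need explicit handling beyond hole-filling.
- The exact tests enumerate nulls; above ~12 observations they switch to
  approximations whose tie corrections are standard but asymptotic.
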