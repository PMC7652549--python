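# nephna — quantitative renal sodium (²³Na) MRI analysis

`nephna` is a Python package for quantifying renal tissue sodium from
²³Na magnetic resonance images. Sodium MRI signal is proportional to
tissue sodium concentration, and the healthy kidney maintains a strong
spatial signature: concentration rises roughly linearly from the cortex
(~70 mmol/L) to the inner medulla (~135 mmol/L). That corticomedullary
gradient is a sensitive readout of renal sodium handling — it flattens
within minutes when a loop diuretic such as furosemide blocks medullary
sodium reabsorption, well before anything changes in blood chemistry.

The package implements the full analysis chain used by multi-site renal
sodium imaging studies, plus a seeded synthetic-data generator so every
stage is testable without scanner data:

- **Phantom calibration** (`nephna.quantify`) — an OLS line through the
  mean signals of in-FOV calibration phantoms of known concentration
  converts signal volumes to concentration maps (mmol/L), with voxelwise
  transmit-B1 correction (double-angle method) and a bulk T1-saturation
  ratio between tissue and phantom material.
- **Concentric-layer segmentation** (`nephna.layers`) — an "onion"
  partition of the kidney mask into N shells by Euclidean distance to the
  organ boundary (mm, anisotropic spacing respected), yielding
  depth-resolved concentration profiles.
- **Gradient estimation** (`nephna.gradient`) — the corticomedullary
  slope in mmol·L⁻¹·mm⁻¹ from an OLS fit of layer mean concentration on
  layer depth, plus dynamic time courses with paired tests against
  baseline.
- **T1 relaxometry** (`nephna.relaxometry`) — voxelwise magnitude
  inversion-recovery fitting |S₀(1 − 2e^(−TI/T1))| and the spoiled
  steady-state saturation factor f = (1 − E)·sin α / (1 − E·cos α),
  E = e^(−TR/T1), used for the calibration correction.
- **Small-sample statistics** (`nephna.stats`) — exact-permutation
  Wilcoxon signed-rank and rank-sum tests, Kruskal–Wallis, Bonferroni
  correction, coefficients of variation and linear fits.
- **Synthetic subjects** (`nephna.synthkid`) — two-compartment
  nested-ellipsoid kidneys with a linear corticomedullary truth profile,
  agar-style phantoms, Rician magnitude noise, smooth B1 fields,
  inter-subject variability, furosemide washout dynamics and flat serum
  panels; NIfTI/YAML output.
- **Study orchestration** (`nephna.pipeline`) — a two-site
  reproducibility study and a dynamic furosemide study, end to end, with
  deterministic JSON reports and CSV tables.

## Worked example

Run the default two-site human study (12 simulated volunteers, 6 per
site, 12 concentric layers) and the porcine furosemide study:

```bash
$ nephna run reproducibility --seed 1 --out out/repro
pooled medulla 133.4 mmol/L, cortex 70.7 mmol/L, whole kidney 91.4 mmol/L
profile fit R^2 = 1.000; max CoV = 5.2%

$ nephna run furosemide --seed 1 --out out/furo
medulla 94.2 -> 71.3 mmol/L (p = 0.0312)
gradient 2.85 -> 0.94 mmol/L/mm
```

The first two lines summarise the reproducibility study: pooled regional
sodium concentrations measured by the full pipeline (signal simulation →
B1 map → phantom calibration → segmentation → regional means), the
coefficient of determination of the cohort-averaged 12-layer
depth-vs-concentration line, and the worst per-site, per-ROI coefficient
of variation. The furosemide lines show the medullary washout over 30
minutes (exact signed-rank p across 6 animals) and the accompanying
flattening of the corticomedullary gradient.

Each run writes `report.json` (all statistics, provenance hash, seed) and
`tables/*.csv`. Synthetic volumes can be exported with
`nephna synth subject|cohort|dynamic|ir ...` (also available as the
`synth` command).

The same studies are available as library calls:

```python
from nephna.pipeline import run_reproducibility_study
report = run_reproducibility_study(seed=1).report
report["pooled"]["medulla"]["mean"]        # 133.4 mmol/L
report["average_profile_fit"]["r_squared"] # 1.000
```

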