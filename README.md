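# parafemur

Parametric statistical shape and appearance modelling of the femur.

Subject-specific femur finite-element models predict fracture load well, but
each one needs a QCT scan and days of model preparation. A *parametric* femur
model sidesteps this: build a statistical model of a corresponded cohort once,
then synthesize realistic whole-femur geometry **and** bone-density
distribution for any requested stature, BMI and age. `parafemur` implements
everything upstream and downstream of the FE solve for that strategy:

- **cohort handling** — load/validate corresponded hexahedral meshes (VTK
  legacy ASCII or `.npz` arrays) with per-element densities and an
  anthropometric table; rigid Procrustes co-alignment (rotation +
  translation, optimised over surface nodes, applied to all nodes — never
  scaling or reflection);
- **density & material** — phantomless muscle–adipose–air HU calibration,
  stitched-scan continuity checks, cortical/trabecular partition at a density
  threshold (default 1.4 g/cm³, surface-shell elements always cortical), and
  configurable `E = a·ρ^b` power laws producing per-element material cards;
- **statistical shape + appearance models** — PCA of the 1/N covariance of
  vectorized nodal coordinates (shape) and element densities (appearance),
  with projection, reconstruction, per-mode variation instances, compactness
  curves, and mode–anthropometry correlation matrices;
- **parametrization** — per-mode ordinary least squares of principal values
  on (stature, BMI, age); predicted contribution factors `b` synthesize new
  instances `s_new = s_mean + Σ b_j · pc_j` on a 13-row mean/±1 SD/±2 SD
  anthropometric grid;
- **morphometrics & evaluation** — femur length, CCD (neck–shaft) angle,
  anterior mid-shaft cortical thickness, mid-shaft cortical cross-section
  area; trendline fits, and the weighted-sum-of-differences (WSD) statistic
  comparing parametric against reference trendline slopes after min–max
  normalization;
- **synthetic cohorts** — a deterministic femur-like hexahedral template
  deformed by calibrated linear anthropometric effect fields, providing exact
  ground truth for end-to-end parameter-recovery tests;
- **leave-one-out** — redundancy analysis of the whole parametrization.

## The model

For each of N corresponded subjects, a channel vector is

```
s_i = (x_1, y_1, z_1, …, x_n, y_n, z_n)ᵀ   (shape)
s_i = (d_1, …, d_m)ᵀ                        (appearance, g/cm³)
```

The model is the eigendecomposition of `D = (1/N) Σ ds_i ds_iᵀ` with
`ds_i = s_i − s_mean` (computed via thin SVD of the centered data matrix),
giving principal components `pc_j` and per-subject principal values
`pv_i = Uᵀ ds_i`. Multilinear regressions `b = F(stature, BMI, age)` map
anthropometry to contribution factors, and new instances are

```
s_new = s_mean + Σ_j b_j · pc_j .
```

Agreement between a parametric model and its reference cohort is scored on
matched trendline-slope pairs `k_yx` (e.g. femur length vs stature): each
slope is normalized by the reference set's observed ranges,
`k_norm = k · Δx_ref/Δy_ref`; pair weights are the per-pair maxima of
|normalized slope| scaled to sum to one; `WSD = Σ w_yx · |k_ref − k_par|`
and `Diff% = 100 · WSD / (max k_ref_norm − min k_ref_norm)`.

## Worked example

Build a parametric model from a synthetic 18-subject cohort with known
anthropometric effects and evaluate it against its own training cohort:

```python
from parafemur import SyntheticCohortSpec, generate_cohort, ParametricFemurModel
from parafemur.evaluation import render_table

spec = SyntheticCohortSpec(n_subjects=18, seed=7)   # default: noisy cohort
samples, truth = generate_cohort(spec)
results = ParametricFemurModel(samples, align=False).fit()
print(results.summary())

tpl = truth.template
report = results.evaluate_morphology(tpl.landmarks, tpl.surface_shell_element_ids)
print(render_table(report))

loo = results.leave_one_out()
print(f"leave-one-out max MAE: {loo.max_mean_abs_coordinate_error:.3f} mm, "
      f"{loo.max_mean_abs_density_error:.4f} g/cm^3")
```

prints (abridged):

```
Parametric femur model (statistical shape + appearance)
============================================================
cohort size:             18
shape dimension:         11520 (3 x nodes)
appearance dimension:    2808 (elements)
retained modes:          17 shape / 17 appearance
covariance convention:   1/N
...
pair                    ref      par        w    w.err
femur_length~stature    1.000    1.002    0.348    0.000
ccd_angle~age        -0.987   -0.989    0.344    0.001
cortical_thickness~age   -0.884   -0.735    0.307    0.046
WSD = 0.047
Diff% = 2.351

leave-one-out max MAE: 0.066 mm, 0.0111 g/cm^3
```

Reading this: the stature→length and age→CCD trends are reproduced almost
perfectly by the parametric model (weighted errors 0.000/0.001); the
age→cortical-thickness trend — the weakest effect relative to this seed's
residual noise — carries nearly all of the disagreement (0.046). The WSD of
0.047 is 2.35 % of the reference cohort's normalized slope range. On a
noise-free cohort (`exact_linear=True`) the same pipeline reproduces the
generator's ground truth to machine precision and WSD drops below 0.005.

The same workflow is scriptable from the shell:

```bash
parafemur synth cohort/ --n-subjects 18 --seed 7
parafemur build-model cohort/ models/ --no-align
parafemur generate cohort/ out/ --grid --no-align
parafemur loo cohort/ --no-align
```

(`--no-align` because synthetic cohorts are generated co-registered; cohorts
digitized in scanner coordinates should keep the default alignment.)

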