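# Methods

This note records the modelling choices behind `parafemur`: the statistical
model and its conventions, the morphometric measurement definitions, the
evaluation statistic, what the synthetic cohort generator does and does not
emulate, and the numerical decisions that affect results.

## Statistical shape and appearance models

Both channels are plain PCA over corresponded vectors: shape stacks nodal
coordinates (length 3n, mm), appearance stacks per-element densities
(length m, g/cm³). The two channels are modelled independently; no combined
shape+intensity vector is formed.

**Covariance convention.** The empirical covariance uses **1/N**, not
1/(N−1). Per-mode principal-value standard deviations follow the same
convention, so `SD_j = sqrt(λ_j)` where `λ_j` is the covariance eigenvalue.
Switching conventions rescales every `SD_j` by √(N/(N−1)) ≈ 1.029 at N = 18;
the convention is stamped into model archives and the results `summary()`.

**Computation.** The decomposition is obtained from the thin SVD of the
centered (N × d) data matrix: if `X_c = A S Bᵀ`, then
`D = (1/N) X_cᵀ X_c = B (S²/N) Bᵀ`. This is algebraically identical to the
dense eigendecomposition of D but costs O(N²d) instead of O(d³); the test
suite verifies equality against a dense oracle on small random cohorts to
1e-8.

**Retained modes.** All nonzero modes are kept (K ≤ N−1 after centering);
eigenvalues below 1e-12 of the largest are treated as numerically zero and
dropped. The compactness curves justify keeping all modes: reconstruction
error decays only gradually with k, so no small subset dominates.

**Sign convention.** Each component is flipped so its largest-magnitude
entry is positive (first such entry on ties). This makes principal-value
signs reproducible across BLAS/LAPACK builds.

**Compactness error metric.** The per-k reconstruction error is the mean
absolute error over all scalar entries — per coordinate for shape, per
element for appearance. A per-node Euclidean alternative is available via
`compactness(..., per_node=True)`; the per-coordinate form is the default
because the shape channel is defined entry-wise.

## Alignment

Procrustes alignment is rigid only: rotation + translation from the closed-
form cross-covariance SVD (Kabsch), with the determinant guard that flips the
smallest singular direction so reflections can never enter. The optimum
minimises the mean **squared** distance between corresponding **surface**
nodes and the transform is applied to all nodes. (A least-absolute-distance
variant has no closed form; least squares is the standard resolution.)
Cohort alignment is a single pass onto a fixed reference member, not an
iterative generalized Procrustes onto an evolving mean. Alignment never
touches density fields.

Cohorts synthesized by this package are emitted co-registered in the template
frame, so pipelines on synthetic data run with `align=False`; aligning them
anyway is harmless for statistics but applies small non-identity rigid
transforms (the samples genuinely differ in shape), which matters only when
comparing coordinates against generator ground truth at machine precision.

## Density calibration and material mapping

The HU→density calibration regresses the median HU of three soft-tissue
reference regions (air, adipose, muscle) against their equivalent
hydroxyapatite densities (−840, −80, 30 mg/cm³) by least squares — three
points over-determine a line, and least squares is the standard resolution.
Preconditions enforce air < adipose < muscle; anything else indicates
mislabeled ROIs.

Stitched multi-scan volumes are screened by the maximum absolute difference
of mean HU between adjacent slabs, flagged above a configurable threshold
(default 30 HU).

Tissue partition: an element is cortical iff its density is **≥** the
threshold (1.4 g/cm³ default; the boundary value itself classifies cortical)
**or** it belongs to the outer-surface shell — thin surface elements are
cortical regardless of density. Density→property mapping uses power laws
`E = a·ρ^b` (defaults: modulus 6850·ρ^1.49 MPa, yield 38.5·ρ^1.48 MPa,
ultimate 42.9·ρ^1.56 MPa — commonly used femoral apparent-density relations,
shipped as *editable configuration*, not as ground truth; any study should
set the coefficients of its own constitutive chain). The element-erosion
strain (default 0.2) and the trabecular strain-rate flag are carried as
metadata for downstream solvers; nothing here computes rate effects or
stress–strain curves. Whether the threshold consumes apparent or ash density
is left to the `DensityField.basis` tag and configuration.

## Parametrization

Each mode's principal values are regressed on an explicit intercept plus raw
(unstandardized) stature, BMI and age by ordinary least squares —
unregularized and convex, hence solver-independent and bitwise deterministic
on refits. Standardized fitting is available behind a flag and folds back to
identical raw coefficients. Because principal values are centered, the
prediction at the cohort-mean anthropometrics is the zero vector, i.e. the
statistical mean femur.

The anthropometric grid has 13 rows: cohort mean, plus each predictor at
±1 and ±2 SD with the others held at their means, by the pure formula
`mean + level·SD`. Individual cells can be pinned through an explicit
clamp-override map (e.g. clamping an extreme cell to a cohort bound);
overrides are never applied silently.

## Morphometric definitions

Reference workflows measure femur morphology interactively in external
tools; this package needs algorithmic definitions. They are defined once on
the template topology via landmark node sets (head, neck, proximal shaft,
mid-shaft, distal, anterior mid-shaft surface patch) and are validated
against the synthetic generator's ground truth — they are not claimed to
reproduce any interactive measurement absolutely:

- **femur length** — distance between the head and distal landmark centroids
  projected on the first principal axis of all nodes;
- **CCD angle** — angle between the proximal-shaft landmark cloud's first
  principal direction (oriented neck-ward) and the neck cloud's first
  principal direction (oriented head-ward), reported on the obtuse (CCD)
  convention;
- **anterior mid-shaft cortical thickness** — rays from the mid-shaft axis
  through the anterior surface patch nodes; per ray, the span of the
  consecutive run of cortical elements ending at the surface
  (ray–hexahedron intersection via Möller–Trumbore on face triangles with
  inclusive tolerances, so grazing hits along shared element edges are
  kept); the patch **average** is reported (a patch mean is more stable than
  any single-point measure);
- **mid-shaft cortical area** — exact plane–hexahedron intersection polygons
  (sign-changing edges + on-plane vertices, angularly ordered, shoelace
  area) summed over cortical elements, on the plane at the midpoint of the
  femur-length measure, perpendicular to the whole-femur principal axis.

All four are rigid-motion invariant; length/thickness scale linearly and
area quadratically under uniform scaling (property-tested).

## Evaluation statistic

Matched trendline-slope pairs are min–max normalized with the *reference*
set's observed ranges, `k_norm = k · Δx_ref/Δy_ref`. Per pair, the weight is
the maximum of |reference| and |parametric| normalized slope — the per-pair
maximum, not a global one — normalized to sum to one; the WSD is the
weighted sum of |reference − parametric| normalized differences, and
`Diff% = 100 · WSD / (max − min)` over the **reference** normalized slopes
only (the parametric series never enters the denominator). The design
penalises disagreement on strong trends and avoids dividing by near-zero
reference slopes. All arithmetic is full precision; `render_table` offers a
3-decimal display for publication-style tables.

## Synthetic cohort generator

**Template.** A schematic femur: an annular hexahedral tube swept along a
piecewise path (flared distal end → straight shaft → bend at the CCD angle →
straight neck → bulged head), default resolution 40 axial stations × 3 radial
element layers × 24 circumferential elements (2808 hexahedra, all corner
Jacobians positive). The wall splits into one inner trabecular layer and a
two-layer cortical shell of fixed geometric span; baseline densities are
1.8 g/cm³ (cortical) and 0.3 g/cm³ (trabecular). With the default
`target_length=430`, the mesh is uniformly rescaled so the measured femur
length is exactly 430 mm. The template is schematic by construction — no
condyles, a tube through the head, simplified cortices — so absolute
synthetic morphometrics are never compared against cadaveric values; only
relative effects and the statistic's arithmetic are.

**Effect structure.** A sample is the template plus a *linear* combination
of fixed displacement fields, one per predictor — so the anthropometry→shape
map is exactly linear, the regime a PCA + multilinear-regression pipeline
must reproduce exactly. Each field realises one effect and is built to leave
the other trendline measures untouched:

- *stature* — centerline-and-outer-radius scaling that preserves the wall
  offsets (so cortical thickness is stature-invariant); calibrated by
  symmetric secant to 246 mm of femur length per metre of stature;
- *age, angle* — linearized in-plane rotation of the neck+head about the
  bend pivot, blended across the bend, with a uniform translation correction
  pinning the head-landmark centroid (decoupling femur length); secant-
  calibrated to −0.581°/yr;
- *age, cortex* — radial thinning of the cortical shell (outer surface and
  inner ring fixed), exactly linear in the thickness measure, −0.073 mm/yr;
  plus a −0.008 g/cm³/yr density offset on cortical elements;
- *BMI* — circumferentially uniform mid-shaft widening (whole node columns
  translate radially; Gaussian axial profile, 0.25 mm per kg/m²), which
  perturbs none of the three trendline measures.

Default anthropometric sampling: stature 161.68 ± 6.99 cm, BMI
27.18 ± 6.09 kg/m², age 57.72 ± 5.61 yr, truncated at ±2.5 SD (emulating a
cohort screened for outliers), n = 18. Residual noise defaults: 0.3 mm iid
per nodal coordinate and 0.05 g/cm³ per element — small enough that the
tissue partition never flips class, large enough that trendline recovery is
a genuinely statistical 3-SE test. `exact_linear=True` zeroes the noise.

**Known cross-talk.** The morphometric functionals are not exactly linear in
the field amplitudes: the rotation field perturbs the whole-mesh principal
axis slightly (femur length residual ≲0.15 mm over the cohort range, <0.1%
of the stature effect) and the linearized rotation leaves a cubic CCD
residual ≲0.2° at the extremes. Parameter-recovery tests therefore carry a
1% relative floor alongside the 3-SE criterion; instance-level recovery
(coordinates and densities against the stored linear ground truth) is exact
to machine precision and is asserted at 1e-6.

**What the generator does not emulate.** Real segmentation/morphing error,
spatially correlated anatomy (noise is iid), left/right asymmetry, cortical
thickness gradients along the shaft, nonlinear age effects, and any
realistic CT intensity structure. Passing tests demonstrate that the
algorithms are correct and the pipeline recovers known effects at the study's
scale and noise level — not that the schematic template spans real femoral
anatomy.

**Recovery criterion.** `recovery_report` regresses each measured
morphometric on (stature, BMI, age) *jointly*, comparing the designated
coefficient to the generator's; the joint fit prevents finite-sample
predictor correlations from leaking one effect into another's univariate
slope. The univariate trendlines (the evaluation statistic's ingredient) are
additionally exercised in the acceptance tests, where the generator's
measure-orthogonal design keeps them unbiased.

## Pipeline and reproducibility

`RunConfig` serializes every convention (covariance normalization, error
metric, cortical threshold, erosion strain, calibration references,
significance threshold 0.01, power-law coefficients, grid overrides, seed)
to JSON, rejects unknown keys, and stamps its digest into every artifact;
re-running a config overwrites artifacts byte-identically. All randomness
flows from a single integer seed through `numpy.random.default_rng`.

Leave-one-out rebuilds both channel models and regressions on N−1 subjects
and regenerates a fixed target list (default: the full-cohort mean and ±1 SD
one-at-a-time rows, 7 instances), reporting the maximum mean absolute nodal
coordinate and density errors over all folds and targets.

Default problem sizes — 18 subjects on the 2808-element template — keep any
single test in seconds while leaving the PCA (17 modes, dimensions 11520 and
2808) and every downstream step statistically non-trivial.

## Known limitations

- Mesh generation from CT segmentations (Kriging/reference-to-target
  morphing), FE fracture simulation, and constitutive-curve construction are
  out of scope; the package stops at material cards and instance meshes.
- The hexahedron cross-section and ray-intersection routines assume
  near-convex elements (true for any usable FE mesh; badly inverted elements
  are caught earlier by the Jacobian check in the generator but not
  re-checked per measurement).
- `pv_anthro_correlations` reports plain Pearson R/p per (mode, predictor)
  pair without multiplicity correction, matching standard exploratory use;
  the 0.01 significance threshold is surfaced in `Trendline.significant`.
- Landmark sets must be supplied for externally produced meshes; there is no
  automatic landmark detection.
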