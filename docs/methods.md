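# Methods

This note documents the models, conventions and numerical choices behind
`frailsvd`, and what the synthetic-data layer does and does not emulate.

## Imaging geometry

All volumes are `VoxelGrid`s: a 3D array plus a NIfTI voxel-to-world
affine. Every geometric quantity — distances, surface areas, volumes — is
computed in world millimetres derived from the affine; voxel units are
never used for measurement. Coordinates follow the RAS convention of the
affine as stored; no reorientation is performed, and registration and
segmentation are upstream of this package (inputs are assumed
co-registered probability maps and masks).

## WMH segmentation post-processing

Probability maps are binarized at a configurable threshold (default 0.10,
**inclusive**, so voxels printed exactly at the boundary are kept). An
optional exclusion mask (e.g. manually delineated cortical infarcts) is
subtracted before component analysis. Lesions are connected components at
configurable connectivity (default 26, the most permissive standard choice
for sparse lesion masks; 6 and 18 available). Components below
`min_lesion_voxels` (default 2) are dropped because single-voxel
components have degenerate surfaces; dropped voxel counts are logged and
the bookkeeping identity `sum(component sizes) + dropped == mask size`
always holds.

## Periventricular / confluent / deep classification

Distance is measured from lesion voxel centers to the nearest
ventricle-mask voxel center with an anisotropy-aware Euclidean distance
transform (`scipy.ndimage.distance_transform_edt` with the voxel spacing
as sampling). A lesion with all voxels within the rule distance (default
10 mm, inclusive) is periventricular; one spanning from within to strictly
beyond is confluent; one entirely strictly beyond is deep. The
center-to-center convention (rather than surface-to-surface) is a choice;
the rule boundary semantics (inclusive "within", strict "beyond") follow
the verbal definition of the categories. The partition is exhaustive and
exclusive by construction, and pooled volumes conserve the total exactly
because volumes are voxel counts times the voxel volume.

## Surface reconstruction and shape descriptors

Each non-degenerate lesion (≥ 4 voxels, voxel centers of full rank) is
meshed by marching cubes at the 0.5 isosurface of its padded binary
subvolume, scaled to mm. The raw marching-cubes surface carries a
staircase artifact that inflates area by several percent and would break
the identity that a convex shape equals its own convex hull; we therefore
apply Laplacian smoothing (λ = 0.5) before measurement. The default is
**20 iterations**: a single pass leaves digitized-ball convexity around
0.96–1.00, while 20 passes bring all three hull ratios to within ~0.001 of
the convex reference with no measurable volume shrinkage, and make the
ratios stable (±0.005) under a 2× change of grid resolution. Smoothing is
configurable, including off.

Shape descriptors come from the smoothed mesh (volume V, area A) and its
convex hull (V_hull, A_hull, computed by qhull on the mesh vertices):

* solidity = V / V_hull  (1 for convex shapes, < 1 otherwise);
* convexity = A / A_hull  (1 for convex shapes, > 1 for rough surfaces —
  this orientation matches descriptors whose group means exceed 1);
* concavity index = (A / A_hull) · (V_hull / V)^(1/3), a combined
  area-and-volume irregularity index equal to 1 for convex shapes and
  increasing with surface complexity.

The three formulas live in a single named strategy ("hull_ratio") in a
registry, so an alternative algebra can be swapped in as one configuration
choice without touching the pipeline. Degenerate lesions (coplanar,
collinear, < 4 voxels) keep their voxel volume but have hull-based
features missing; they contribute to volume sums but not to shape means.

**Fractal dimension** is the Minkowski–Bouligand box-counting estimate on
the lesion's boundary voxel set (lesion voxels with at least one
background 6-neighbor): boxes of edge {1, 2, 4, 8, 16} voxels (clipped to
the lesion extent) that intersect the boundary are counted on the tight
bounding box, and the estimate is the least-squares slope of log N(s)
against log(1/s). This yields exactly 1.0 for a straight line and ≈ 1.96
for the boundary shell of a digitized ball of radius 16 (the smooth-surface
limit is 2; the residual deficit is finite-size box granularity). Denser
box ladders (adding sizes 3, 6, 12) were evaluated and rejected: they
introduce systematic wiggle into the fit that swamps small complexity
differences. Lesions spanning fewer than two boxes at the smallest size
get a missing value.

**Eccentricity** uses the eigenvalues λ₁ ≥ λ₂ ≥ λ₃ of the covariance of
voxel-center mm coordinates: ecc = √(1 − λ₃/λ₁) — 0 for a ball,
√(1 − 1/4) ≈ 0.866 for a 2:1:1 ellipsoid, approaching 1 for a needle.

**Per-subject aggregation** pools periventricular + confluent lesions
(volume; mean solidity, convexity, concavity index, fractal dimension)
and deep lesions (volume; mean eccentricity, fractal dimension), with
lesions weighted equally in the means. Subjects without lesions in a
group get zero volume and missing shape means there.

## Perfusion

CBF is quantified voxelwise with the single-compartment pCASL model
(formula in the README). Defaults: τ = 1650 ms and PLD = 1525 ms (the
acquisition timing of the emulated protocol), and consensus kinetic
constants λ = 0.9 ml/g, α = 0.85, T1b = 1650 ms; all are configurable
because sites differ. The model is linear in ΔM and exactly invertible —
the ASL phantom is built by that inversion, so quantification recovers the
ground-truth CBF to floating-point round-off.

ROI means are arithmetic means over mask voxels, excluding voxels masked
for non-positive M0 (counted and reported). Spatial CoV uses the
population (n) standard deviation over GM voxels divided by the mean; at
the voxel counts involved the n vs n−1 distinction is negligible, and the
ratio is invariant under global rescaling, so raw perfusion-weighted and
quantified CBF inputs give identical values (the input kind is recorded in
the result). Visual QC gating is an input label: `cbf_contrast` scans
contribute ROI means and CoV, `vascular_contrast` scans CoV only,
`no_contrast` scans nothing. No automatic contrast classification is
attempted.

## Frailty scoring

Component rules: slowness = TUG strictly over 10 s; weakness = grip at or
below the sex × BMI-stratum cutoff (the canonical phenotype table ships as
an editable YAML config, not hard-coded constants); weight loss = ≥ 5% or
≥ 3 kg self-reported in the previous year (both inclusive); exhaustion and
mobility are pre-computed boolean inputs, because the underlying
questionnaire item/combination rules are defined upstream. Classification
is a pure function of the count (0 / 1–2 / ≥ 3), so permuting which
components are positive can never change the category. Derived
demographic flags: obesity = BMI ≥ 30; depressive symptoms = HADS
depression subscale ≥ 8.

## Statistical models

* Volumes are transformed ln(100 · V ml) before regression. Zero volumes
  are undefined under the transform and are excluded from volume models
  with a logged count — no epsilon offset, which would introduce an
  arbitrary constant.
* Group contrasts (frail vs non-frail, pre-frail vs non-frail) are
  indicator coefficients in one OLS fit with the non-frail group as
  reference, adjusted for age and sex (female = 1), plus intracranial
  volume for volume outcomes. Solidity is transformed ln(100 · x) like a
  volume; other shape features enter untransformed.
* Confidence intervals are normal-theory Wald intervals; p-values are
  two-sided coefficient tests. No multiple-testing correction is applied —
  each contrast is reported at its own p against the 0.05 convention —
  and this is stated in every summary.
* Lacunar-infarct presence uses maximum-likelihood logistic regression,
  reported on the odds-ratio scale. Complete or quasi-complete separation
  is flagged and the interval reported as unavailable rather than as a
  spurious number.
* Secondary shape models add ln(100 · V_total) to the covariates and
  report the attenuation ratio β_adjusted / β_unadjusted, quantifying how
  much of a shape–group association is carried by volume.
* Exploratory models regress each feature of interest on one frailty
  component (0/1) plus age and sex (plus ICV for volumes).
* Demographics: mean ± sd with one-way ANOVA for continuous variables,
  median (IQR) with ANOVA for MMSE, n (%) with chi-square for categorical
  variables (expected-zero cells flagged). Identical constant groups give
  the F = 0 boundary, reported as p = 1.
* Listwise deletion per model; each reported n equals the rows complete
  for that model's variables, and per-outcome exclusion counts are carried
  in the results object.

The statistics layer follows the statsmodels idiom: `FrailtySVDModel`
(from a DataFrame or CSV) → `.fit()` → `FrailtySVDResults` with the
fitted tables, `summary()` and `save()`. The imaging, phantom and frailty
modules are deliberately *not* forced into that shape — they are
deterministic pipeline stages, not fitted models.

## Synthetic data: what it emulates and what it does not

**Image phantoms** rasterize parametric lesions by voxel-center inclusion
(probability 0.9 inside, 0 outside, optional Gaussian blur for threshold
testing), so analytic volumes and convex references are exact before any
smoothing. Families: ball, ellipsoid, line, plus-cross, and a
perturbed blob — a ball whose radius is modulated by a seeded real
spherical-harmonic field of degrees 2–12, normalized to 3 standard
deviations of the field (so amplitude has the same physical meaning for
every seed) and clipped to ±1. Amplitude 0 is exactly convex; increasing
amplitude strictly increases the concavity index and the boundary fractal
dimension across seeds, which is the property the morphometry suite
exercises. Degrees were chosen so the grid resolves the induced
concavities: lower-order fields (≤ 4) deform the blob without roughening
it, and a seed-dependent (max-based) normalization lets one spike
suppress all other roughening. Lesion overlap and grid-boundary contact
are errors, because either would corrupt the ground truth. Phantoms do
not simulate scanner physics, FLAIR/T1 contrast, motion, or the behavior
of any segmentation algorithm.

**ASL phantoms** invert the quantification model exactly; they do not
simulate labeling physics, transit artifacts or noise.

**Cohort tables** are generated from the same model families the analysis
fits: ln(100 · V_total) linear in group indicators, age (truncated normal
≥ 65 per group), sex, ICV, optionally one component effect, with Gaussian
residuals (default σ = 1.2 on the ln scale, a realistic spread for
WMH volumes); lacunar presence logistic in the group indicators with no
covariate effects by default, so conditional and marginal odds ratios
coincide; shape features group-conditional normals with an optional
`volume_shape_coupling` slope on centered ln-volume (default 0 — the
cohort model treats shape and volume as conditionally independent given
group, since no generative covariance is established; the knob exists so
attenuation behavior can be exercised). Raw frailty measurements are
generated consistently with each subject's component flags (e.g. TUG
above/below 10 s, grip relative to the subject's own stratum cutoff), so
re-scoring them reproduces the group exactly. Default group sizes
(30/85/55), age and sex distributions, effect sizes (0.69/0.43 on
ln-volume; odds ratios 1.25/1.35; slowness effect 0.65 when enabled) and
feature means emulate an elective-surgery cohort of adults aged 65+.

Because generator and fitted model agree, passing recovery/coverage tests
demonstrates the *inference machinery* is correct and calibrated — it
does not demonstrate robustness to model misspecification, measurement
error, or segmentation noise, all of which real data have.

## Problem sizes and determinism

Everything is seeded (`numpy.random.default_rng`); identical seeds give
bit-identical phantoms and cohorts. The test and acceptance workloads use
phantom grids of 32³–64³ voxels, blob radii around 12 voxels, and
150–1000 replicated cohorts of n = 170 for coverage and calibration —
sizes at which every check runs on one CPU in minutes while keeping
Monte-Carlo error well below the decision margins (e.g. binomial sd of a
95% coverage estimate over 150 replicates ≈ 1.8 percentage points).

## Known limitations

* The shape-descriptor algebra is one defensible convention among
  several in use; the strategy registry exists precisely because printed
  descriptor definitions vary between groups.
* Box-counting FD on small lesions is granular; values for lesions a few
  voxels across carry substantial discretization noise (hence the
  minimum-size rule and missing values rather than unstable estimates).
* The periventricular rule uses voxel-center distances; a
  surface-distance convention would shift boundaries by up to half a
  voxel diagonal.
* No partial-volume correction, multi-PLD modeling, mixed models,
  imputation or multiplicity control — deliberately out of scope.
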