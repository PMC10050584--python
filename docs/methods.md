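# Methods

`ptpdomics` re-creates, end to end, a radiomics + dosiomics workflow for
predicting any-grade post-treatment pneumonitis (PTP) after thoracic
stereotactic body radiotherapy (SBRT): phantom cohort synthesis,
voxel-wise EQD2 conversion, VOI construction, texture feature
extraction from CT and 3D dose grids, bootstrapped Boruta feature
ranking, SMOTE class rebalancing, and nested cross-validated classifier
comparison.  Real SBRT cohorts of this kind are private; the package
therefore ships a synthetic-cohort generator whose statistical structure
matches what the analysis assumes, so every downstream stage is testable
without any data download.

## Phantom cohorts

Each case is a 64x64x48-voxel grid at 2x2x3 mm (configurable; the tests
and the acceptance script use 48x48x32 at the same spacing with
proportionally smaller anatomy — the quoted problem sizes are the
package's own desk-scale choice).  Anatomy is deliberately schematic —
two ellipsoidal lungs in a soft-tissue body ellipsoid — because the
pipeline contract depends on mask geometry and voxel statistics, not on
anatomical realism.  A spherical GTV (radius 7–13 mm by default) is
placed wholly inside one lung (bounded rejection sampling; an
unplaceable GTV raises an explicit error).  The PTV is the GTV expanded
by a margin drawn uniformly in (0, 5] mm using the same spacing-aware
distance-transform expansion as the analysis VOIs.

Fractionation draws a per-fraction dose uniformly from 5–15 Gy and a
fraction count from {3, 5, 8}.  Dose is a prescription plateau over the
PTV with a sigmoidal falloff in signed distance from the PTV surface
(50% isodose 14 mm outside the surface, 7 mm penumbra width — chosen to
resemble a steep SBRT gradient, not fitted to any plan), multiplied by
a correlated speckle field of 8% relative amplitude.  CT combines tissue
base values (air −1000 HU, body +30 HU, lung −800 HU, tumor +20 HU),
global correlated noise (25 HU), and an extra texture field in the
peri-PTV lung shell (60 HU at scale 1).

Clinical covariates (age, sex, KPI, tumor location, immune checkpoint
inhibitor therapy, prior chemotherapy) are sampled to match the marginal
distributions of a typical SBRT cohort of 110 patients with 24 events.
Tumor size is taken as the actual GTV volume in mm^3 (cohort tables in
this literature sometimes print sizes in "cc" with magnitudes that only
make sense as mm^3; the generator avoids the ambiguity by using explicit
mm^3).

### Planted outcome signal

Two per-case standard-normal latents carry the outcome signal:

* `z_dose` multiplies the *correlation length* of the dose speckle
  (coarser vs finer texture, factor `exp(0.35 z)`).  After applying the
  speckle, the dose grid is rank-remapped onto the smooth falloff's
  exact value multiset, stratified by the DVH evaluation region (lung
  minus GTV vs the rest), so lung DVH metrics are invariant to this
  dial *by construction*, while the spatial texture that
  GLCM/NGTDM/zone statistics read carries the signal.  Without the
  remap, coarser speckle inflates the variance of Vx (and value swaps
  across the lung boundary survive even a grid-wide remap), letting a
  flexible classifier read the texture latent out of DVH columns.
* `z_ct` multiplies the *amplitude* of the peri-PTV CT shell texture
  (factor `exp(0.5 z)`).

Labels come from a noisy logistic utility
`u = b_dose z_dose + b_ct z_ct + b_age z_age + logistic noise`; the
`n_events` cases with the largest utilities are labelled positive, so
prevalence is exact for every seed.  With all coefficients zero the
ranking is pure noise and labels are exchangeable.  The "planted"
preset uses `b_dose = b_ct = 2.5`, which puts the latent/label
point-biserial correlation near 0.5 — a strong but not deterministic
signal.  What passing tests show about real data is limited: the
phantoms prove the pipeline can find a texture-coded signal without
leaking, not that SBRT cohorts contain one.

## EQD2 and DVH metrics

Voxel-wise linear-quadratic conversion `EQD2 = D (d + α/β)/(2 + α/β)`
with `α/β = 3` Gy for lung.  `d` is the voxel's own per-fraction dose
(`D / n_fractions`), consistent with a voxel-basis conversion; a uniform
prescription fraction dose can be forced through `fraction_dose=`.
At `d = 2` Gy the conversion is the identity to machine precision.
DVH metrics (mean dose, V5–V50) use the inclusive `>=` convention and
report percent of VOI volume; they are computed on the total lung minus
GTV (the GTV exclusion is switchable by passing a different VOI).  Dose
outside the lung is ignored at VOI evaluation time — the dose grid is
never zeroed, which keeps the PTV + 2 cm VOI well defined.

## VOIs

Three analysis VOIs: total lung minus GTV, ipsilateral lung minus GTV,
PTV + 2 cm isotropic margin.  Margin expansion thresholds a Euclidean
distance transform computed with the physical spacing, so a millimetre
margin is isotropic on anisotropic grids and is clipped at grid bounds.
Laterality: the lung with the larger GTV voxel overlap; exact ties break
toward the larger overlap fraction and then toward the left lung; for
central tumors with no overlap the lung with the nearer centroid is
chosen (a package convention — clinical reports rarely define it).  The
PTV + 2 cm VOI is not intersected with the lungs by default
(`intersect_ptv_with_lung=True` for sensitivity analyses).

## Feature registry

Exactly 104 features per (modality, VOI): 13 shape, 18 first-order,
22 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM — the default catalog of
the common open-source radiomics engines, with GLCM MCC excluded (costly
eigen-decomposition) and SumAverage excluded (equal to twice
JointAverage for symmetric matrices).  Three VOIs give 312 columns per
modality; dose grids are treated as images with Gy as grey levels, and
physical and EQD2 dose are separate modalities.

Numerical conventions worth knowing:

* Discretization: fixed bin width (25 HU for CT, 0.5 Gy for dose,
  recorded in the provenance sidecar), floor binning referenced to the
  VOI minimum, occupied bins relabelled to contiguous levels 1..Ng.
  A constant region is a single level, not an error.
* GLCM: symmetric matrices for the 13 unique offsets at Chebyshev
  distance 1; features computed per offset and averaged.  Single-level
  limits are fixed: Correlation = Idn = Idmn = 1, InverseVariance = 0.
* GLRLM: runs along the 13 directions, averaged.  GLSZM zones and GLDM
  dependences use 26-connectivity; the GLDM dependence index counts the
  centre voxel, so it starts at 1.  NGTDM neighbour means use in-VOI
  26-neighbours only.
* Shape: surface area (and the volume inside Sphericity and
  SurfaceVolumeRatio) from a marching-cubes mesh of the lightly
  smoothed mask (Gaussian sigma 0.8 voxels — raw binary meshing carries
  a staircase bias of several percent; a face-stepping estimator is
  kept as `face_surface_area_mm2` for cross-checks).  Axis lengths are
  4*sqrt of the principal moments of the voxel-centre cloud; degenerate
  VOIs fall back to Elongation = Flatness = 1.
* No resampling to isotropic voxels; all formulas are spacing-aware.
* Any non-finite feature value (degenerate VOI) is imputed as 0 with a
  warning, so downstream tables never contain missing values.

Every matrix-family feature is validated against independent
brute-force enumeration oracles (plain nested loops over voxels and
matrix cells) on random grids up to 5^3.

## Feature selection

Per feature set: Pearson intercorrelation filter (|r| > 0.7; among a
violating pair, the feature with the larger mean absolute correlation
to all remaining features is dropped, ties toward the lexicographically
larger name; constant columns are kept) followed by Boruta, repeated
over stratified bootstrap resamples (1000 by default; the tests and the
acceptance script scale this down).  The filter runs inside every
bootstrap by default (`filter_per_bootstrap=False` applies it once
globally).  Boruta appends a shuffled shadow copy of every live
feature, fits a random forest, scores a hit when a real feature beats
the best shadow importance, and applies two-sided binomial tests on
accumulated hits with a Bonferroni adjustment over the tested features
(the reference R implementation's convention; without it, features with
persistent spurious in-sample correlation are over-confirmed).
Importance defaults to Gini impurity — the random-forest default in the
R ecosystem and an order of magnitude cheaper inside a bootstrap loop —
with permutation importance as an option.  Tentative features count as
not selected.  Features are ranked by confirmation frequency; the final
set keeps the top `m` features, `m` being the median confirmed count
over runs rounded half-up, with frequency ties broken by mean
importance and then name.  For combined feature sets the per-group
final sets are concatenated and the same procedure runs again.

## Class rebalancing

SMOTE with the classic oversample/undersample semantics: per minority
sample, `perc_over/100` synthetic points on segments to one of its
`k = 3` nearest minority neighbours (Euclidean metric on z-scored
columns, synthetics mapped back to the original scale);
the majority class is then downsampled without replacement to
`perc_under/100` times the synthetic count (capped at availability).
Defaults 200%/200%: n_min = 10 yields 30 minority + 40 majority rows.
Resampling is applied to training portions only — outer and inner
training folds — never to any test fold.

## Nested cross-validation

100 iterations (scaled down where noted) of stratified 5-fold nested
CV: hyperparameters by grid search on 5 inner folds (mean
inner-validation AUC — the reporting metric, chosen for consistency),
winner refit on the outer training set, scored once on the untouched
outer test fold.  A 110-case cohort yields 88:22 outer and modally
70:18 inner splits.  Four classifiers: random forest, elastic-net
logistic regression, RBF SVM, and LogitBoost implemented as stagewise
Newton boosting over depth-1 regression trees (no established
implementation exists in the Python ecosystem).  Scaling is fit on the
(resampled) training fold only; optional per-fold feature selection
runs inside the outer training set.  AUC uses the Mann–Whitney
formulation with ties counting 1/2.  Models are ranked 1–4 per
(iteration, fold) with average ranks on ties.  Summary CIs are
t-intervals across outer-fold AUCs (how such CIs are aggregated is a
genuine choice; per-fold records are also exported so any other
aggregation can be recomputed).  Single-class outer test folds are
skipped and counted; stratification makes them rare.  When a model's
grid holds exactly one configuration the inner search is skipped — its
argmax is trivial — which the scaled-down validation runs exploit.

A statistical caveat that shaped the validation design: at n = 110 the
cross-validated AUC of a flexible classifier on *null* data fluctuates
from cohort to cohort with a standard deviation near 0.08, because each
finite cohort carries fixed spurious feature–label correlations (and
its mean sits slightly below 0.5 — the familiar pessimistic
small-sample CV bias).  Harness-level null calibration therefore
re-permutes the (exchangeable) zero-effect labels on every iteration,
so the mean averages over label draws and converges to 0.5 unless
information leaks; and chance-level claims for the DVH/clinical sets
are estimated as means over independent cohort draws rather than from
a single cohort.

## Known limitations

* Phantom anatomy and dose falloff are schematic; absolute feature
  values are not comparable to clinical cohorts.
* The 104-feature catalog is a reconstruction of the de-facto standard
  registry, not a copy of any specific study's supplementary list.
* Boruta false-confirmation behaviour depends on the importance
  estimator; with impurity importance and small cohorts the null median
  confirmed count is small but not zero.
* No external validation data exists for the synthetic setting by
  construction.
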