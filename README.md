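# ptpdomics

Radiomics + dosiomics machine-learning pipeline for predicting
post-treatment pneumonitis (PTP) after thoracic stereotactic body
radiotherapy (SBRT), exercised entirely on synthetic thoracic phantoms
with a planted outcome signal.

Pneumonitis after lung SBRT is dose dependent, but dose–volume
histogram (DVH) summaries discard the spatial arrangement of the dose.
Treating the 3D dose distribution as an image ("dosiomics") and
combining it with CT texture ("radiomics") can improve risk prediction.
This package implements that full workflow for researchers in outcome
modelling and medical image analysis:

1. **Phantom cohorts** (`ptpdomics.synthetic`) — two-lung anatomy, a
   spherical GTV expanded ≤5 mm to a PTV, SBRT-like dose falloff with
   fraction doses of 5–15 Gy, clinical covariates, and exact event
   prevalence (default 24/110).  A logistic label model plants dose- and
   CT-texture signal with controllable strength.
2. **Dose biology** (`ptpdomics.dose`) — voxel-wise conversion to the
   equivalent dose in 2 Gy fractions under the linear-quadratic model,
   `EQD2 = D · (d + α/β)/(2 + α/β)` with `α/β = 3` Gy for lung, and DVH
   metrics (mean dose, V5–V50).
3. **VOIs** (`ptpdomics.roi`) — total lung minus GTV, ipsilateral lung
   minus GTV, and PTV + 2 cm isotropic margin via spacing-aware
   distance transforms.
4. **Features** (`ptpdomics.features`) — a frozen 104-feature registry
   (shape, first-order, GLCM, GLRLM, GLSZM, GLDM, NGTDM) evaluated per
   VOI and modality: 104 × 3 VOIs = 312 columns per modality (CT,
   physical dose, EQD2 dose).
5. **Selection** (`ptpdomics.selection`) — Pearson intercorrelation
   filter (cutoff 0.7) and Boruta shadow-feature selection inside
   stratified bootstrap runs; features ranked by selection frequency,
   final set size set by the median confirmed count.
6. **Class balance** (`ptpdomics.balance`) — SMOTE (k = 3, 200 %
   oversampling, 200 % undersampling), applied to training folds only.
7. **Evaluation** (`ptpdomics.evaluate`) — 100 × 5-fold nested
   cross-validation of four classifiers (random forest, elastic-net
   logistic regression, RBF SVM, LogitBoost) with grid search in the
   inner folds, AUC reporting, 1–4 rank aggregation and 95 % t-CIs.
8. **Orchestration** (`ptpdomics.pipeline`, CLI `ptpdomics`) — YAML
   config, NIfTI + CSV-manifest cohort format, nine feature-set recipes
   (radiomics / dosiomics / clinical / DVH and their five combinations).

## Worked example

```python
import numpy as np
from ptpdomics import (EffectSpec, generate_cohort, build_vois,
                       extract_feature_table, bootstrap_select,
                       nested_cv_evaluate)
from ptpdomics.synthetic import PhantomParams

params = PhantomParams(shape=(32, 48, 48), spacing=(3.0, 2.0, 2.0),
                       lung_semiaxes=(45.0, 28.0, 18.0),
                       lung_centers_frac=((0.5, 0.5, 0.28), (0.5, 0.5, 0.72)),
                       body_semiaxes=(60.0, 46.0, 46.0),
                       gtv_radius_range=(6.0, 11.0))
cases = generate_cohort(110, 24, EffectSpec.planted(), seed=0, params=params)
vois = [build_vois(c) for c in cases]
y = np.array([c.label for c in cases])

ct = extract_feature_table(cases, vois, "CT")          # 110 x 312
dose = extract_feature_table(cases, vois, "DOSE_PHYS") # 110 x 312

report = bootstrap_select(ct, y, n_boot=20, seed=0, max_iter=20)
print(report.median_confirmed, report.final_set)

from sklearn.ensemble import RandomForestClassifier
cv = nested_cv_evaluate(
    ct[report.final_set], y, n_iter=5, seed=0,
    models={"rf": RandomForestClassifier(n_estimators=300)},
    grids={"rf": {"max_features": ["sqrt", 0.25]}},
)
print(round(cv.mean_auc("rf"), 2))
```

With seed 0 this prints a median confirmed count of 4 and the final set

```
4 ['CT__LUNG_IPSI__glcm__ClusterProminence',
   'CT__LUNG_TOTAL__glszm__GrayLevelNonUniformity',
   'CT__PTV2CM__firstorder__Median',
   'CT__LUNG_IPSI__glcm__ClusterShade']
0.7
```

— four CT texture features from the tumor-adjacent VOIs, reaching a
mean nested-CV AUC of 0.70 on their own.  Running the same procedure on
the dose modality and on the concatenation of both preselected sets
(see `scripts/acceptance.py`) yields the characteristic ordering:
combined radiomics + dosiomics ≈ 0.80–0.86, each single-modality set
below it, and DVH / clinical features at chance (≈ 0.44–0.52 averaged
over cohort draws).  The planted signal lives in the textures, not in
dose–volume or clinical covariates, and the pipeline recovers exactly
that ordering.

A shell workflow is available through the CLI:

```bash
ptpdomics simulate --n 110 --events 24 --seed 7 --effect planted --out cohort/
ptpdomics extract --manifest cohort/manifest.csv --modalities ct,dose --out features/
ptpdomics evaluate --features features/features_CT.csv --labels features/labels.csv \
    --iters 20 --out results/
```

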