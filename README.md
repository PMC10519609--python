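# oralcyto

Marker-integrated oral cytopathology analysis: a tested, reusable pipeline
for risk-stratifying oral lesions from brush-biopsy cytology.

Oral potentially malignant disorders (OPMDs) span benign lesions to lesions
on the verge of invasive carcinoma, and conventional oral cytology is too
subjective to separate them. This package implements a marker-based
alternative: fluorescent cytology images (DAPI plus lectin/glycoprotein
channels such as SNA-1 and CD44) are segmented into single cells, each cell
is scored for nuclear–cytoplasmic morphometry and marker expression, an
atypia classifier flags suspicious cells, and per-patient statistical
aggregates feed a classifier that separates low-risk lesions (LRL:
benign / hyperplasia / mild dysplasia) from high-risk lesions (HRL:
moderate–severe dysplasia + carcinoma). A diagnostic-marker meta-analysis
engine — the tool used to choose the marker panel in the first place — is
included, as is a synthetic-data module that generates every input the
pipeline needs, so the whole stack is testable without any patient data.

## What's inside

| module | contents |
|---|---|
| `oralcyto.simdata` | synthetic cytology fields with ground-truth masks, synthetic patient cohorts, synthetic meta-analysis study sets |
| `oralcyto.metadx` | per-study odds ratios / mean differences, DerSimonian–Laird random-effects pooling, Cochran's Q / I² / τ², Moses–Littenberg summary ROC, marker-panel selection filter |
| `oralcyto.scoring` | intensity grading on the {0,2,4,6} scale, composite score (% positivity × modal intensity, 0–600), per-patient marker features, site × age healthy-baseline nomogram, ROC utilities |
| `oralcyto.imaging` | Otsu + watershed nucleus/cell segmentation, cell/cluster/artefact triage, regionprops morphometry, patient-level aggregation |
| `oralcyto.atypia` | `CancerNetClassifier`, a compact NumPy CNN (3 blocks of 3×3 conv–BN–ReLU with a 1×1 conv before each max-pool; 4/8/16 filters; global average pooling; sigmoid head; Adam + binary cross-entropy), plus a deterministic rule-based atypia scorer |
| `oralcyto.stratify` | Kruskal–Wallis screening, VIF pruning, logistic / PCA+L2 logistic / random forest / SVM / gradient-boosting models with 3-fold CV tuning on a stratified 70/30 split, Clopper–Pearson exact CIs, two-proportion sample size |
| `oralcyto.cli` | `oralcyto` command with subcommands for every stage |

The statistical core in brief. For k studies with effects
y_i (log OR or mean difference) and variances v_i, fixed-effect weights are
w_i = 1/v_i, Q = Σ w_i (y_i − ŷ_FE)², and the DerSimonian–Laird
between-study variance is τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw));
random-effects weights are 1/(v_i + τ²) and I² = max(0, 100·(Q − (k−1))/Q).
The summary ROC regresses D = logit(TPR) − logit(FPR) on
S = logit(TPR) + logit(FPR) and integrates the implied TPR(FPR) curve.
A marker enters the panel when it has ≥3 studies, non-significant
heterogeneity (p ≥ 0.05), a significant pooled effect, pooled OR > 5 and
summary AUC > 0.75.

## Worked example

```python
from oralcyto.simdata import CohortSimConfig, simulate_cohort
from oralcyto.stratify import ModelSpec, fit_and_evaluate

cohort = simulate_cohort(CohortSimConfig(n_per_class=(50, 50, 50), seed=3))
report = fit_and_evaluate(cohort, ModelSpec(kind="logistic_vif", seed=3))
print(report.test_metrics)
print(report.tp, report.fn, report.tn, report.fp)
print(report.ci["sensitivity"])
```

prints

```
{'sensitivity': 1.0, 'specificity': 1.0, 'accuracy': 1.0, 'auc': 1.0}
30 0 15 0
(88.42966917779722, 100.0)
```

i.e. on a 150-patient synthetic cohort the tuned logistic model classifies
the 45-patient held-out split (30 HRL / 15 LRL, the stratified 30% with
round-half-up class counts) perfectly, and the exact Clopper–Pearson 95%
interval for 30/30 sensitivity is 88.4–100%. Synthetic cohorts are far
cleaner than patients, so treat these numbers as a pipeline check, not a
clinical claim (see `docs/methods.md`).

The same flow from the shell:

```bash
oralcyto simulate-cohort --out cohort.csv --seed 3
oralcyto classify cohort.csv --out report.json --kind logistic_vif --seed 3
oralcyto simulate-images --out-dir imgs --n-cells 25 --seed 5
oralcyto features imgs/image_000.tif --out cells.csv
```

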