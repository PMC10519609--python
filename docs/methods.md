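# Methods

This note documents the models implemented in `oralcyto`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish.

## Problem setting

Brush-biopsy cytology of oral lesions yields multi-channel fluorescent
images: a DAPI nuclear counterstain plus up to two marker channels
(lectins such as SNA-1 and MAA that bind aberrant sialylation, and
immunostains such as CD44 and Cyclin D1). The clinical task is two-class:
separate low-risk lesions (LRL — benign, hyperplasia, mild dysplasia) from
high-risk lesions (HRL — moderate/severe dysplasia plus carcinoma), where
histology is the reference standard. The pipeline has four layers: marker
selection by meta-analysis, per-cell scoring, image automation, and
patient-level classification.

## Meta-analysis engine (`metadx`)

Per study the effect is a log odds ratio from a 2×2 extraction
(marker-positive/negative × dysplastic/non-dysplastic) with the
Haldane–Anscombe correction — 0.5 added to all four cells only when that
study has a zero cell — or an unstandardised mean difference with variance
sd₁²/n₁ + sd₂²/n₂ for continuous scores. Pooling is inverse-variance:
fixed-effect, or DerSimonian–Laird random-effects with the moment
estimator τ² = max(0, (Q − df)/(Σw − Σw²/Σw)). When τ̂² = 0 the two
coincide exactly (a unit test asserts this, and the DL path is
cross-checked against `statsmodels.stats.meta_analysis.combine_effects`,
which is never used as the implementation). Heterogeneity is reported as
Cochran's Q with a χ²(k−1) test and I² = max(0, 100·(Q−df)/Q), clamped to
[0, 100]. Confidence intervals use z = 1.959964 on the working scale and
are exponentiated for odds ratios.

The summary ROC is the unweighted Moses–Littenberg regression of
D = logit(TPR) − logit(FPR) on S = logit(TPR) + logit(FPR); the AUC
integrates TPR(FPR) = expit((a + (1+b)·logit(FPR))/(1−b)) by trapezoid
over the FPR grid 0.001…0.999 (step 0.001). Degenerate regressors
(var(S) ≈ 0, e.g. duplicated operating points) fall back to b = 0,
a = mean(D); |b| ≥ 1 makes the curve undefined and raises an error that
carries the fitted a, b. The marker filter requires k ≥ 3 studies,
heterogeneity p ≥ 0.05, pooled p < 0.05, and — for dichotomous markers —
pooled OR > 5 and summary AUC > 0.75; continuous markers have no OR/sAUC
scale, so they are judged on count, homogeneity and significance.
Weighted Moses–Littenberg, bivariate HSROC models and small-study bias
statistics are out of scope.

## Scoring model (`scoring`)

Cell intensity is measured as the background-corrected mean over the cell
(or nucleus) mask, where the background is the mean of all pixels outside
every cell label. Corrected intensities map to the even grade scale
{0, 2, 4, 6} at thresholds (0.25, 0.5, 0.75) on the normalised scale —
the grading in practice is visual, so these cut points are calibratable
defaults, not measured constants. The composite slide score is
percentage positivity × modal intensity (range 0–600); the modal grade is
taken over positive cells with ties broken toward the higher grade
(conservative toward positivity). Patient-level marker features are:
SNA1avg/SNA1max and MAAavg over per-cell grades, CD44max, CD44% (strictly
above grade 4, i.e. grade 6 only), and nuclear-positivity percentages
(CD44N+, CyclinD1N+), where a cell is nuclear-positive when its
nucleus-mask corrected marker mean reaches the first grading threshold.
An absent channel leaves its features missing, never zero. Whether
patient averages should be taken over grades or raw intensities is not
settled; grades are the default here and raw intensities remain available
from the CellRecord table. The nomogram tabulates healthy-baseline mean,
population SD and mean + 2·SD per marker for each anatomical site
(buccal, tongue, gingiva) × age group (≤40, >40); strata with fewer than
two samples are flagged incomplete rather than given a bound.

## Imaging (`imaging`)

The published segmentation/triage networks for this assay are not
distributable, so the reference implementation is a deterministic
classical pipeline behind the same interfaces: nuclei by Otsu threshold
on the Gaussian-smoothed DAPI channel, hole filling, and a
distance-transform watershed with peak separation ≥ 5 px and minimum
nucleus area 30 px²; cytoplasm by a watershed on the smoothed sum of the
marker channels, seeded at nuclei and constrained to the Otsu foreground.
Triage is rule-based: a connected cell region with ≥2 nuclei is a
cluster, with none (or failing area ∈ [80, 50000] px² / solidity ≥ 0.5
bounds) an artefact, otherwise a single cell. Morphometry comes from
`skimage.measure.regionprops`: nucleus/cell ratios of area, equivalent
diameter, perimeter, major and minor axis; solidity, orientation
(radians, (−π/2, π/2], image-axis convention), eccentricity and convex
area for both compartments; background-corrected channel means per mask.
Patient aggregates are average, maximum and population SD per feature
plus the fraction of cells with atypia probability > 0.5 and the mean
atypia probability. Crops for the atypia classifier are 64×64, median
filtered (3×3).

## Atypia classification (`atypia`)

`CancerNetClassifier` is a compact CNN written directly in NumPy
(im2col convolutions with hand-derived backward passes, verified against
numeric gradients in the test suite). The published description fixes the
ingredients — 3×3 filters with ReLU and batch normalisation, 4/8/16
filters per block, a 1×1 convolution before each max-pool, three blocks
(27 layers) before global average pooling, binary cross-entropy, Adam,
batch size 16 — but not the exact 27-layer composition; the stack
implemented here is, per block, [3×3 conv → BN → ReLU] ×2 followed by
1×1 conv → BN → ReLU and a 2×2 max-pool, then global average pooling and
a dense sigmoid head, which totals 27 such layers and is documented as an
interpretation. Crops are min-max normalised per crop. The default
schedule is 30 epochs (the full 150 is one parameter away); the learning
rate default is 3·10⁻³. Optional on-the-fly augmentation implements the
usual rotation / shift / shear / zoom / flip set. A deterministic
logistic scorer over the N/C area ratio, expit((r − 0.3)/0.05), serves as
an independent oracle and as a fallback when no trained weights exist;
θ = 0.3 sits between the simulator's normal and atypical N/C
populations. Transfer learning from large pretrained backbones is out of
scope (it overfits at this data scale).

## Risk stratification (`stratify`)

Patients are the unit of analysis throughout (no per-cell leakage). The
evaluation protocol is a seeded stratified 70/30 split with round-half-up
per-class test counts — with 79 HRL / 55 LRL this reproduces a 24/17 test
composition — followed by 3-fold cross-validated hyperparameter tuning on
the training side only; standardisation is fit on training data only (a
test asserts the scaler's means equal the training means and differ from
the pooled means). Model families: unpenalised logistic regression after
Kruskal–Wallis screening (p < 0.05, uncorrected — a deliberate,
documented choice) and iterative VIF pruning (drop the highest VIF while
any exceeds 10, VIF_j = 1/(1−R²_j), +∞ for perfect collinearity);
PCA + L2 logistic regression (components and C tuned); random forest
(500 trees, depth/features tuned); RBF-SVM and gradient boosting as
optional kinds. Sensitivity, specificity and accuracy carry exact
Clopper–Pearson 95% intervals (low = Beta(α/2; k, n−k+1) quantile,
high = Beta(1−α/2; k+1, n−k)); the AUC carries a Hanley–McNeil
normal-approximation interval, since no exact interval exists for an
AUC. The two-proportion sample size uses the classical normal
approximation with pooled p̄ under the null; 70% vs 96% positivity at 80%
power and two-sided α = 0.05 gives 32 per group.

## Synthetic data (`simdata`)

Every generator is a pure function of its config, seed included, so all
bundles are bit-reproducible. Images: cells are ellipses with semi-axes
uniform in 14–24 px and uniform orientation; nuclei are concentric
(jittered) ellipses kept fully interior with ≥1 px margin. The N/C area
ratio is truncated-normal — Normal(0.18, 0.05) on (0.05, 0.4) for normal
cells, Normal(0.45, 0.08) on (0.2, 0.9) for atypical cells — values
chosen to give clearly separated but overlapping classes; atypical nuclei
additionally receive a smooth radial boundary perturbation (±12%). Marker
intensities are class-dependent normals on the normalised [0, 1] scale,
rising with grade for SNA-1 and MAA, with class-dependent nuclear
positivity probabilities for CD44 and Cyclin D1; rendering is ideal
intensity → Gaussian PSF blur (σ = 1 px) → additive Gaussian noise
(σ = 0.02), and the truth table records pre-noise values and
pixel-counted N/C ratios. Clusters are 2–3 overlapping cells forming one
connected region; artefacts are nucleus-free perturbed blobs. Placement
is rejection sampling with 1000 tries per object before an explicit
error.

Cohorts: per-class feature means follow the progression contract
(SNA-1 rising LRL→HGD→OSCC, CD44 nuclear positivity lowest in LRL, MAA
and Cyclin D1 highest in carcinoma) with within-class SDs of ~0.6–0.7
grade units (8–9 percentage points for percent features); CD44 features
carry a site × age baseline offset (+0.8 grade units in tongue and
gingiva above age 40). Clinical covariates: age ~ N(44, 13) clipped to
19–80, buccal-dominated site mix (60/25/15%), tobacco-habit probability
rising with grade (0.55/0.75/0.80). Configs whose effect directions
contradict the contract are rejected; flat (null) settings are allowed
for calibration tests. Meta-study sets draw per-study true log-ORs from
N(θ, τ²), arm sizes and control rates from uniform ranges, and fill the
2×2 table binomially with the case rate obtained by a logit shift.

## What the synthetic tests show — and what they don't

The simulators emulate the geometry, intensity ordering and cohort
structure of the assay, not its hard parts: no out-of-focus planes,
uneven illumination, debris, blood cells, staining batch effects,
overlapping chromatin texture, or label noise in the reference standard.
Segmentation recovery (≥95% detection at IoU ≥ 0.8, N/C-ratio MAE
< 0.05), CNN accuracy (≥90% on held-out crops) and classifier operating
points (sensitivity/specificity ≥ 80% on default cohorts) therefore
establish that the implementation is correct and self-consistent at the
study's operating regime — not that these numbers transfer to patients.
Cohort-level clinical performance cannot be reproduced here at all, since
no patient images or tables are publicly deposited.

## Numerical choices and problem sizes

Tolerances: printed statistics are checked to their printed precision;
geometric checks allow for rasterisation (e.g. a disk's hull solidity is
~0.96, not 1). Ties: modal grade breaks high; the Youden cutoff breaks
toward the lower threshold. Degenerate inputs: blank channels give empty
masks; one-pixel masks flag the record invalid; identical samples give
H = 0, p = 1 in the rank test. Default problem sizes keep a full
verification run at desk scale on one CPU: 3 fields of 30 cells at
640×640 for segmentation recovery, 600/200 crops × 30 epochs × 3 restarts
for the CNN, and 5 cohorts of 150 patients for the end-to-end check
(about 10 minutes in total, CNN training dominating).
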