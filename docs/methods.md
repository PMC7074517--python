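# Methods

This note documents the models, the numerical choices, and the
limitations of `fusionda`, in the order the pipeline runs.

## Synthetic cohort generator

**What it emulates.** A case-control serum-biomarker study: 16 cases and
12 controls by default, 37 analytes in three platform blocks (27-plex
bead panel; 4 automated immunoassays — CRP, MPO, FGF21, BDNF; 6
extracellular-vesicle immunoblot markers — CD9, CD63, CD81, ATP5A,
NDUFS3, SDHB). Seven analytes (CD9, NDUFS3, CRP, FGF21, IL9, MIP-1β,
TNF-α) carry arm-specific published medians and interquartile ranges;
the other 30 are null analytes with identical arms.

**Distribution family.** Per analyte and arm, a log-normal
`X = exp(μ + σZ)`. Rationale: serum cytokine and densitometry data are
strictly positive and right-skewed, and the log-normal admits a closed-
form match to the only available summaries: μ = ln(median),
σ = asinh(IQR/(2·median))/z₀.₇₅ with z₀.₇₅ = 0.6744898. An IQR of 0
degenerates gracefully to a point mass.

**Defaults that are choices, not data.**
* Null analytes get median 100, IQR 50 in both arms (units arbitrary);
  autoscaling removes location and scale, so any shared value is
  equivalent.
* Analytes are independent by default. A Gaussian-copula correlation
  hook (`CohortConfig.correlation`) exists for sensitivity studies but
  ships off — no covariance information is available to parametrize it.
* The NDUFS3 case entry is typeset as "96.8 ± 128.0" (a mean ± SD amid
  median(IQR) rows) in the source table; it is read as median 96.8,
  IQR 128.0. Consistent handling was preferred over guessing a
  different distribution for one cell; the ambiguity is noted here and
  not otherwise resolved.
* MPO and BDNF units (ng/mL) are nominal; both are null analytes, so
  the unit never reaches a computation.
* Demographics (age, BMI) are not generated; they are not inputs to
  the multivariate pipeline.

**What it does not emulate** (and what passing tests therefore do not
show about real data): between-analyte correlation, assay detection
limits and censoring, batch effects, technical replicates, and any
non-log-normal tail behavior. The generator reproduces published
*medians and IQRs*, not full distributions.

**Known consequence of the family choice.** Matching median/IQR makes
the CD9 control arm extremely skewed (σ ≈ 1.49). On the raw measurement
scale this compresses CD9's *linear* standardized mean difference to
d ≈ 0.45 even though its rank separation (AUROC ≈ 0.95) is enormous. A
linear classifier on raw values therefore cannot fully exploit CD9; the
overall out-of-fold accuracy of the default pipeline on default
synthetic cohorts sits near 72–75%, not the ≈94% a log-scale analysis
of the same cohorts would reach. The pipeline deliberately applies no
monotone transform, because the modeled protocol autoscales raw values
only; users analyzing real skewed data may pass log-transformed tables
in themselves.

## Fusion

Autoscaling uses training mean and SD (n−1 denominator — conventional
for small-n chemometric data); each block is then divided by the
Frobenius norm of its autoscaled training submatrix, giving every block
unit total variance; blocks are concatenated. All parameters are learned
from training rows only. By default the scaling is refit inside every
cross-validation training fold; `RDCVConfig(refit_scaling=False)`
reproduces the one-shot variant in which the full dataset is scaled once
before splitting (closer to a published single-pass analysis, but mildly
leaky). A zero-variance analyte raises an error naming the analyte:
silent dropping would desynchronize VIP/RP indices, and silent epsilons
would hide degenerate designs.

## PLS-DA

NIPALS PLS1 with X-deflation only; y is mean-centered during fitting and
the intercept restores the original scale. The composite coefficient
vector is b = W(PᵀW)⁻¹q; predictions via b agree with the sequential
latent-variable expansion to ~1e-15 (tested), and at A = rank(X) they
coincide with least squares. Class coding is control = 0 / case = 1 with
threshold τ = 0.5; classification is *strictly greater than* τ, so a
prediction exactly at the threshold goes to the control class. τ is
configurable; the midpoint of the coding is the neutral default. If the
X–y covariance is exhausted before the requested number of components
(low-rank X), extraction stops early and the model records the count
actually extracted.

## Repeated double cross-validation

Defaults: 30 repetitions, 7 stratified outer folds, 5 stratified inner
folds, candidate components 1..10. Fold counts are feasibility-driven
choices for n = 28 with a 16/12 split (7 outer folds give test folds of
4 with both classes present in every training set); they are
configurable. The inner criterion is the total inner-CV
misclassification count, ties to the smaller A (parsimony under the
pipeline's primary merit). Merits are computed per repetition on the
pooled out-of-fold predictions — per-fold AUROC on 4 samples would be
meaningless. Per-class percent correct is averaged across repetitions
(SD with n−1). One master seed spawns per-repetition substreams
(`numpy.random.SeedSequence`), so runs are reproducible bit for bit.

## Permutation test

Labels are permuted and the identical rDCV merit pipeline is re-run per
randomization. Default 1 repetition per permutation: the null merit is
unbiased either way and only its Monte-Carlo spread differs;
`perm_repetitions` can be raised to mirror the observed pipeline
exactly. P-values use the add-one estimator, so p = 0 is impossible and
the resolution floor is 1/(n_perm+1). Extremeness is one-sided per
merit: smaller NMC, larger AUROC and DQ2. When the observed statistic is
computed with the same number of repetitions as the nulls, observed and
null are exchangeable under the no-signal hypothesis and the p-value is
(super-)uniform; AUROC, being the least discrete merit, is the one whose
rejection rate tracks the nominal level most closely (NMC's heavy ties
make its test conservative). Null-calibration checks therefore read
chance-level behavior from seed-averaged summaries: a single 28-sample
null cohort can be genuinely somewhat separable by luck of the draw.

## VIP and rank product

VIP is computed on a reference model fit to all samples at the median of
the component counts selected across all rDCV segments (halves truncated
downward — the more parsimonious reading). Σ VIP² = p is maintained to
1e-8 and tested. Rank products rank |b| per segment with average ranks
on ties, and take the geometric mean as exp(mean(log rank)) to avoid
overflow over hundreds of segments. The candidate signature is the
VIP > 1 set ordered by ascending RP, truncated to k (default 7); both
full score tables are always reported alongside, since any cutoff on
"inspection"-style scores is a convention.

Because the 28-sample cohort is fixed across all segments, a null
analyte that is by chance correlated with the labels in *this* draw
stays near the top in every segment; single-cohort signatures therefore
typically mix true effects with one or two lucky nulls. That is a
property of small-n resampling on a fixed cohort, not of the estimator;
recovery statements in the tests are made across independent cohort
seeds.

## SIMCA

One class (the cases) is modeled by PCA on within-class autoscaled data
(SVD; score variances with n−1). T² is the score-space Mahalanobis
distance, Q the squared reconstruction residual. Both are divided by
their calibration 95th percentiles — linear-interpolation empirical
quantiles (`numpy.percentile` default), a fixed, bit-reproducible
estimator choice. The combined distance d = √((T²_red)² + (Q_red)²)
accepts at d < 2 (strict). Out-of-class samples are transformed with the
*class* model's scaling — a one-class model has nothing else. If a
reduced statistic's calibration percentile is numerically zero (Q at
full PC rank), that statistic is defined as 0 rather than 0/0.

Component selection maximizes cross-validated efficiency
√(sensitivity × specificity) over 1..A_max: venetian-blinds folds over
the in-class samples (deterministic, sensible for exchangeable rows);
held-out in-class samples give pooled CV sensitivity; out-of-class
samples are scored against each fold's model and their per-fold
rejection rates averaged — the averaging convention is a documented
choice. Ties go to fewer components. By default SIMCA runs on the full
concatenated analyte table; `simca_block="ev_immunoblot"` restricts to
the EV block for analyses focused on vesicle cargo.

## Pipeline

`run_all` executes simulate/load → rDCV → permutation (skippable with
`n_perm=0`) → ranking → SIMCA, logs dimensions and seeds at stage
boundaries, embeds a SHA-256 digest of the resolved config in the
report, and writes JSON + CSV outputs. Identical configs produce
byte-identical reports.

## Problem sizes used in the test suite

The suite exercises the method at its native scale (n = 28, p = 37, 30
repetitions). Aggregate calibration checks use 5 cohort seeds for
chance-level classification, 200 null cohorts × 99 randomizations for
permutation-p uniformity, 20 cohort seeds for recovery statements, and
1e5 draws per arm for generator-calibration medians; these sizes give
Monte-Carlo error comfortably inside the asserted tolerances while the
whole suite runs in minutes on one CPU.

## Known limitations

* The generator's independence assumption makes the discriminant
  problem easier than correlated real panels in some respects (no
  redundant signal) and harder in others (no correlated noise to
  exploit); recovery rates on real data will differ.
* DQ2 is computed on pooled out-of-fold predictions per repetition, not
  per fold; with 28 samples this is the only stable option, but it is a
  convention.
* The rDCV does not nest the choice of preprocessing variants or of τ;
  only the component count is selected inside the inner loop.
* SIMCA models only the case category; a complementary control-class
  model (multi-class SIMCA) is out of scope.
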