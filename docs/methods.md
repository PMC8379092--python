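# Methods

`diffperf` implements a machine-learning analysis for discriminating
vascular mild cognitive impairment (vMCI) from cognitively normal
small-vessel-disease patients using region-wise diffusion (DTI) and
perfusion (ASL-CBF) features, together with a synthetic cohort
generator that makes every stage testable without clinical data. This
note records the model, the design choices made where the design was
genuinely open, the numerical details, and the known limitations.

## The analysis

**Features.** Subjects are described by 308 atlas-wise means: FA, MD,
AD and RD over the 48 ICBM-DTI-81 white-matter labels (192 diffusion
features) and CBF over the 116 AAL gray-matter labels (116 perfusion
features). The package treats all features as unitless reals; the
conventional 1e-4 mm^2/s display scale for diffusivities is the
caller's concern. Columns are named `modality__metric__region`.
Features are standardized inside every fit using only that fit's rows,
so any global rescaling of a column is immaterial to selection and
classification.

**Nested 10 x 10 feature selection.** The cohort is split into 10
outer folds, stratified on (diagnosis, sex). Each outer fold is a
*testing pool*: its reduced feature set is computed from the other
nine folds only, by splitting them into 10 stratified inner folds,
fitting a least-squares lasso (response: the 0/1 diagnosis label) with
internally cross-validated penalty on each inner fold's training
portion, and taking the union of the ten supports. The union
deliberately over-includes: any feature important for some subsample
survives to the classification stage, which re-sparsifies.

**Classification.** For each subject, an L1-penalized logistic
regression P(y=1|z) = 1/(1+exp(-w'z^)) (z^ the standardized feature
vector augmented by 1; intercept unpenalized) is trained on all other
subjects, restricted to the subject's pool's reduced features, and
evaluated on the held-out subject — leave-one-out cross-validation in
which no subject ever influences the feature set or the model that
scores it. The logistic penalty is chosen once per pool by 10-fold CV
on the subjects outside the pool. Predictions are thresholded at 0.5;
ROC curves and AUC summarize ranking quality; McNemar's test compares
paired classifiers (chi-square with continuity correction at >= 25
discordant pairs, exact binomial below).

**Consensus features.** A feature's frequency is the fraction of the
LOOCV models giving it nonzero weight; features at frequency >= 0.75
(inclusive) form the consensus set. Counting nonzero classifier
weights rather than reduced-set membership is deliberate: pool-shared
reduced sets can only produce frequencies that are sums of pool
fractions, whereas observed consensus tables report values such as
0.982 that only per-model counting can produce. Both semantics are
implemented (`count="model_weights"` default, `"reduced_sets"`
optional).

**Associations.** Partial Pearson correlations between consensus
features and attention-executive scores (TMT-A, TMT-B, Stroop C-T,
VFT), computed within a diagnostic group with sex, age and education
residualized out by least squares; p from the t transform with
df = n - 2 - 3. Benjamini-Hochberg correction is applied within each
cognitive test across features (the grid is reported per test); a
whole-table family is available as an option. Group comparisons for
demographic/feature tables use a Lilliefors normality gate at
alpha = 0.05 per group (plain KS against a fitted normal is
anti-conservative), then Welch's t-test or the Wilcoxon rank-sum test;
sex uses Pearson's chi-square without continuity correction.

## Choice of the penalty rule

How the lasso penalty was "estimated by default" is the one genuinely
under-determined step of the published analysis; CV-minimum, the 1-SE
rule, and a fixed path point are all plausible readings, and all are
available via `LassoConfig.selection_rule` /
`SparseLogisticConfig.selection_rule`. The package default is the
**1-SE rule for both stages** (largest penalty whose CV error is
within one standard error of the minimum, SE taken across fold means,
as in glmnet). The reason is empirical and structural: at n = 113 and
p = 308 the CV-minimum linear lasso returns saturated supports (~100+
features per inner fit, reduced sets of 100-160), and a CV-minimum
logistic stage then yields consensus sets of 20-35 features. That
regime contradicts the sparsity the method is designed to deliver
(consensus sets of ~13 of 308) and measurably degrades false-positive
control on synthetic cohorts; under the 1-SE default the consensus
size and frequency profile match the intended operating regime.

## The synthetic cohort generator

The generator emulates the study's feature tables, not its images:

- 74 cases / 39 controls; age ~ N(65.97, 6.84) for cases and
  N(63.44, 7.04) for controls truncated to [50, 85]; education ~
  N(10.5, 2.6) truncated at >= 6 years; sex ~ Bernoulli(0.77) in both
  groups (so stratified folds exercise small female strata).
- 13 planted discriminative features with the published group means
  (8 CBF, 4 FA, 1 AD); group SDs are not published, so the common SD
  of each planted feature defaults to |Delta mean| / 0.8 — Cohen's
  d = 0.8, strong but realistic for effects that survive FDR at
  n = 113 — and is configurable (`effect_d`).
- Background features: per-metric baseline mean/SD (FA 0.42 +/- 0.035,
  MD 8.0 +/- 0.5, AD 12.5 +/- 0.7, RD 6.0 +/- 0.5 on the 1e-4 scale,
  CBF 45 +/- 8 mL/100g/min) and exchangeable correlation rho = 0.3
  between any two background features of the same modality, realized
  through one latent factor per modality. Planted features carry
  independent noise: if they loaded on the shared factor, background
  features would hold genuine conditional (noise-canceling) signal and
  "false positive" would stop being well defined for the generator.
- Cognitive scores match the published group means/SDs. Within the
  case group, seven (feature, test) pairs carry planted partial
  correlations (given sex/age/education) at the published values
  (e.g., right-ACR FA vs TMT-B at r = -0.404). Scores are linear
  combinations of the standardized planted features (coefficients
  a = sqrt(v) R^-1 r, solved in closed form so each pair's population
  partial correlation equals its target after the covariate share v is
  excluded), small covariate effects (3% of variance each), and
  Gaussian noise.

What the generator does **not** emulate: the real data's full
covariance (only exchangeable within-modality structure), lesion
burden and WMH volumes, non-Gaussian feature marginals, floor/ceiling
effects in cognitive scores (scores are not truncated, so extreme
draws can be implausible), and any genuine background-feature signal.
Passing recovery tests therefore shows the pipeline finds the kind of
signal the generator plants under realistic dimensionality and
correlation — not that it would behave identically on clinical data.

### An honest limit of false-positive control

On cohorts drawn at the default conditions, the consensus set recovers
a median 11 of 13 planted features (20 seeds), but the median
false-positive count is 3-4, with a heavy upper tail (up to ~15 on
unlucky seeds), not the <= 2 one might hope for. The mechanism is
instructive: the shared within-modality factor realizes a nonzero
sample correlation with the diagnosis label (typically |r| ~ 0.1 at
n = 113) in each drawn cohort. That chance association holds across
the *whole* cohort, so internal cross-validation — which can only see
held-out folds of the same cohort — confirms it, and clusters of
factor-correlated background features enter the models stably.
Stability selection across LOOCV folds cannot remove it either,
because all folds share 112 of 113 subjects. This is a cohort-level
confounding floor that no within-cohort penalty rule can cross; only
external replication could. The acceptance suite pins this number so
regressions are visible.

## Numerical choices

- Linear lasso: cyclic coordinate descent on the Gram matrix of the
  standardized design (objective (1/2n)||y - b0 - Xb||^2 + lambda
  ||b||_1), with an active-set Newton step as accelerator (kept only
  when it lowers the objective, with backtracking) and a full KKT pass
  admitting violators; convergence at max coefficient change < 1e-7
  (`tol`). Coefficients are reported on the input scale; |b| < 1e-12
  is treated as zero for support purposes. Zero-variance columns are
  dropped (standardized to zero) inside each fit.
- Penalty path: 100 geometric values from lambda_max = max_j
  |<x_j, y>|/n down by factor 1e-4. Fits along the CV path stop early
  once training R^2 >= 0.999 (saturated; smaller penalties inherit the
  solution, which CV can never prefer) and use a relaxed tolerance of
  1e-4 (`cv_tol`) — the CV curve only ranks penalties, and its fold
  noise dwarfs coefficient precision far below that. Final fits always
  use the full tolerance.
- Logistic lasso: IRLS with weighted coordinate descent inner solves,
  weights clipped at 1e-5; a run whose linear predictor exceeds 100 in
  magnitude is reported as non-converged (perfect separation needs
  lambda > 0). Penalty grid: 25 geometric values down by factor 0.01.
- Ties on the CV curve break toward the larger (sparser) penalty; the
  1-SE rule takes the largest penalty within one SE (across fold
  means) of the minimum.
- All randomness is keyed to sorted subject ids plus integer seeds
  (fold assignment per stratum, CV splits, stage seeds derived from
  the run seed via a fixed SeedSequence rule), so file row order never
  changes any result and every stage is reproducible in isolation.
- Degenerate inputs: single-class subsets, constant responses,
  rank-deficient covariates and zero marginals raise typed errors; an
  inner lasso that selects nothing contributes the empty set to the
  union; a pool with an empty reduced set predicts the training base
  rate for its members with a warning.

## Problem sizes used by the test and acceptance runs

Stage-level tests run on a 64-subject, 42-feature cohort with three
planted effects. The pipeline-level recovery surface uses the full
default conditions (113 subjects, 308 features): 7 seeds for the
d = 0.8 consensus-recovery medians and 5 seeds for the d = 2.0
accuracy check in the test suite; the acceptance script uses 5 and 3
seeds respectively, plus 20 seeds for association recovery, 400
null cohorts for t-test calibration and 150 for FDR calibration.
These sizes put the medians within one unit of their 20-seed values
while keeping a full run in minutes on one core.

## Known limitations

- The lasso feature-selection response is the 0/1 label treated as
  real (least squares), mirroring the published pipeline; a
  logistic-loss selection stage is intentionally out of scope.
- The sparse logistic classifier is L1-penalized maximum likelihood,
  not the Bayesian ARD formulation the original SLR toolbox used; the
  two coincide in their operating idea (exact zeros in w) but not in
  their posterior machinery.
- McNemar's test compares paired 0.5-threshold classifications; it is
  not an AUC-difference test (DeLong is a non-goal).
- No probability calibration, no multi-class support, no elastic-net
  mixing, no imputation (missing cells are errors by design).
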