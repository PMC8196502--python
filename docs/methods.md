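# Methods

## The screening problem

Coronary heart disease (CHD) screening from echocardiography rests on the
observation that ischemia degrades myocardial deformation before it is
visible on ECG or to the eye. Two-dimensional speckle-tracking
echocardiography (2D-STE) quantifies that deformation per left-ventricular
segment. `chdstack` models the resulting tabular problem: 71 predictors
per subject — peak systolic strain (PSS), systolic strain rate (SSR) and
time-to-peak (TP) over the standard AHA 17-segment model, radial global
strain at three short-axis levels × three myocardial layers, layer-specific
global longitudinal peak strain (GLPS), the peak standard deviation of
time-to-peak (PSD), plus age and six binary risk factors — and a binary
CHD label (angiographic stenosis ≥ 50%).

## The two-step stacking estimator

Let `c_1 … c_L` be the 0/1 outputs of L base classifiers for one subject.
Majority voting classifies positive when `mean(c_l) ≥ 0.5`; weighted
voting when `Σ w_l c_l ≥ 0.5`, where the weights may be negative. Stacking
generalizes weighted voting: the combination rule is itself learned, on a
validation set disjoint from the base classifiers' training data, from the
L-vector of base predictions. Here the combiner is a random forest, so the
"weights" are not literal coefficients; the decision rule is *meta-learner
score ≥ 0.5*, with the score defined as the fraction of trees voting
positive. All ties at exactly 0.5 classify positive — the `≥` convention
is applied uniformly (voting rules, stack decisions, final decision).

The two-step estimator repeats first-step stacking K times on resampled
splits and stacks the stacks:

1. Hold out a test set (15%) and a second-step validation set
   ("validation 0", 20% of the remainder) once.
2. For k = 1…K, split the remaining training pool into a first-step
   training set (80%) and validation set (20%); fit the L base
   classifiers on the training part and the first-step meta-learner on
   their validation-part predictions.
3. Collect the K first-step stack outputs on validation 0 and fit the
   second-step meta-learner on them against the validation-0 labels.

With 424 subjects (217 positive) this yields the canonical sizes
64 / 72 / 288 and ten (230, 58) pairs. Test subjects never enter any fit;
`fit_stack` refuses overlapping train/validation subject sets outright.

Defaults: L = 14, K = 10, meta-learner inputs are hard 0/1 predictions
(`stack_on="labels"`, matching the voting formulation; `"scores"` feeds
continuous base scores instead).

### Meta-learner settings

Both meta-learners are random forests with 500 trees and
`min_samples_leaf=5`. The leaf floor matters: the meta problem is tiny
(14 or 10 near-binary columns, 58–72 rows), and fully grown trees simply
memorize the validation set, which drags stacking below plain vote
averaging. A coarse leaf keeps the forest close to a smoothed voting rule
while still allowing learned, possibly non-monotone combinations. Seeds
for every stochastic learner derive from one base seed by fixed offsets,
so any fitted model is exactly reproducible.

### Base-classifier registry

Nineteen method families are registered under their field names, from
logistic regression through kernel SVMs, Gaussian processes and small
neural networks to gradient boosting, each as a scikit-learn pipeline
(standardization + estimator) with a small tuning grid (≤ 12
configurations, stratified k-fold CV). Four families are documented
adapters: the cumulative probability model degenerates to binary logistic
regression for a two-class outcome; the Bayesian GLM is a ridge-prior
(MAP) logistic regression; the weighted subspace random forest is a
random forest tuned over aggressive per-split feature subsampling; the
monotone MLP is a tanh MLP, and the model-averaged neural network
soft-averages three independently initialized MLPs. Margin classifiers
(SVMs) expose their ROC score as a logistic squash of the signed decision
margin — monotone, hence AUC-equivalent to the margin itself.

A screening rule excludes base methods whose accuracy falls below 60%.
Applied to the reference accuracy table bundled with the registry (the
mean test accuracies observed for the 19 methods in the motivating
clinical study), it retains 14 methods and excludes five (random forest,
weighted subspace random forest, K-nearest neighbor, sparse LDA,
stochastic gradient boosting); those 14 are the default ensemble roster.
`filter_by_accuracy` implements the rule generically, so the screen can
equally be run on accuracies measured on one's own validation set —
measuring them on a *test* set, as a literal reading of the original
protocol suggests, leaks test information and is not the default here.

The replicated harness uses the registry defaults without per-replicate
grid search (`tune=False`): with 14 methods × 11 fits per replicate,
tuning multiplies runtime several-fold while the tuned and default
configurations are nearly indistinguishable at these sample sizes. CV
tuning is fully implemented and switchable (`EnsembleConfig(tune=True)`).

## Preprocessing

**t-test screen.** Per-feature two-sided two-sample t-tests between
classes, Welch by default (the pooled-variance variant is a flag; the
original report says only "two-sample t-test", and Welch is the safer
default under unequal variances). Features with p ≤ α (default 0.05) are
flagged. If both classes have zero variance the p-value is defined as 1
with a `degenerate` flag rather than crashing. No multiple-testing
correction is applied by default, matching the raw-p-value reporting
convention of the source protocol. Group-level screening
(`effect_pattern_check`) collapses each feature group to its per-subject
mean before testing; how the original grouped radial p-values were
computed is not documented anywhere, so this is a declared choice.

**Block PCA.** Each 17-segment block (PSS, SSR, TP) is reduced
separately. The decomposition is of the correlation matrix by default
(strain blocks mix %, 1/s and ms scales); covariance PCA is a flag.
Loadings come from `numpy.linalg.eigh` with eigenvalues clipped at zero
and each column's sign fixed so its largest-magnitude element is positive
— fitted models are therefore bit-stable. Component counts: fixed rule
PSS→3, SSR→3, TP→2 (the canonical choice), or an elbow rule
(argmax over j of λ_j/λ_{j+1}). PCA is fitted on training subjects only
and applied to validation/test by projection; in the replicate harness it
is refitted per replicate on that replicate's training pool. With the
defaults, 71 predictors become 28 (71 − 3×17 + 3 + 3 + 2).

**Splits.** All partitioning is stratified by label. Per-stratum sizes
use round-half-up on `stratum_n × frac`, reconciled to the round-half-up
overall target by adjusting the larger stratum; this reproduces
424 × 0.15 → 64 and 288 × 0.20 → 58 exactly. The named parts (test,
validation 0) must contain both classes; the K resampled first-step
splits only follow the size arithmetic, since on very small cohorts a
size-1 validation part cannot be stratified. The K first-step splits are
drawn as independent stratified resamples of the pool (whether the
original design used a partition family instead is unstated; independent
resampling is the declared choice).

## Synthetic cohort generator

The generator emulates the *conditions* of the study cohort, not its
data. Defaults: n = 424, prevalence 217/424 with labels assigned by exact
count (the fixed case/control design, which also makes split sizes
deterministic), per-class age means/SDs and binary risk-factor rates
matching the published baseline table (e.g. smoking 52.5% in cases vs 28%
in controls).

Strain features are multivariate Gaussian — continuous measurements to
which t-tests and PCA are applied exactly. The correlation model is a
two-level block design reflecting the qualitative correlation structure
reported for these features: apical/apex segments highly correlated
(0.70), basal/mid moderately (0.50 for PSS, 0.35 for SSR), TP uniformly
0.60, a PSS↔SSR coupling of 0.20, radial layers 0.50 within a short-axis
level and 0.10 across levels, GLPS layers 0.80. The implied 64×64
correlation matrix is validated by Cholesky factorization at
construction; an invalid configuration raises rather than being repaired.

Class effects are mean shifts in SD units per feature group: PSS 0.25,
SSR 0.22, GLPS 0.30, zero for TP, the radial groups and PSD. They were
calibrated analytically from the published significance pattern (a group
p ≈ 0.002 at ~212 subjects per class corresponds to a standardized shift
of ≈ 0.30, and so on) so that a t-test screen at n = 424 reproduces the
longitudinal-significant / radial-null pattern in most seeds. They are
calibrated parameters, not estimates of the real cohort's effect sizes.

What the generator deliberately does **not** emulate: non-Gaussian tails
and floor effects of real strain measurements, missingness, correlation
between clinical covariates and strain (smoking is independent of PSS
here), vendor- and operator-specific measurement structure, and any
nonlinear class boundary. Consequently, passing tests demonstrate that
the pipeline's machinery is correct under its stated assumptions — not
that the headline clinical performance (87.7% accuracy on the private
cohort) transfers; on this linear-Gaussian cohort the ensemble reaches
~0.62 accuracy against a 0.512 prevalence baseline, and the nearly
optimal linear base classifiers leave stacking little headroom, so the
three ensembles finish within a percent or two of each other.

## Evaluation protocol

Accuracy, sensitivity and specificity come from the confusion matrix;
ROC/AUC from the threshold-swept curve (trapezoidal AUC, equal to the
pairwise concordance probability with ties half-weighted). Vote-based
methods are scored by their continuous ensemble score (mean vote /
accuracy-weighted vote / meta score), not hard labels, so curves have
more than three points.

`run_replicates` redraws the **entire** split plan per replicate
(replicate r seeds everything with `base_seed + r`) and runs all
requested methods on identical splits — a paired design that sharpens
method contrasts. Mean ± SD uses the n−1 denominator; SD is reported as
NaN for R < 2. Weighted voting weights are the base classifiers'
validation-0 accuracies normalized to sum to one. The GLPS-only ablation
restricts predictors to the three GLPS layers (no PCA) under the
identical protocol.

Problem sizes used by the shipped checks: the replicated comparison runs
at n = 424 with R = 20 (ordering property) and R = 5 (acceptance script);
generator-fidelity checks run at n = 10,000.

## Known limitations

- The 19 base methods are adapter-mapped to scikit-learn; no claim is
  made that their hyperparameter spaces match any other software's
  defaults.
- Gaussian-process classifiers use fixed kernels (no marginal-likelihood
  optimization) to keep fits deterministic and fast at these sample sizes.
- The generator's independence between clinical covariates and strain
  features means clinical variables carry real signal only through their
  own per-class rates.
- `sensitivity`/`specificity` are NaN when the relevant truth class is
  absent (possible only in tiny unstratified subsets).
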