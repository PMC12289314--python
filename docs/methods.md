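# Methods

## Problem

Given a tabular snapshot of an inpatient encounter — maximum medication
dosages, binary procedure indicators, and most-recent lab values over an
observation window — retrieve the k most similar patients from a reference
cohort and predict two binary outcomes (hospital-acquired AKI onset, 1-year
post-discharge mortality) by majority vote. The package compares five
autoencoder (AE) variants as representation learners for this retrieval,
two distance families (Euclidean, learned Mahalanobis), and the
hyperparameters that govern them.

## Autoencoder family

All variants share one 3-layer architecture: an encoder
`Z = phi1(X W^T + b)` to a latent space of dimension
`l = max(1, round(ratio * m))` and a decoder `X' = phi2(Z W'^T + b')`,
with phi in {sigmoid, relu} applied to both layers. They differ only in
input corruption and loss:

| variant | loss |
|---|---|
| AE  | `MSE(X, X')` |
| DAE | `MSE(X, g(f(X_noise)))`, swap noise on the input |
| CAE | `MSE + lambda * ||J_f(X)||_F^2` |
| SAE | `MSE + beta * KL(rho, rho_hat)` |
| RAE | `-MCC(X, X') + beta * KL(rho, rho_hat) + lambda * ||W||^2 / 2` |

Conventions that the equations leave open, fixed here:

- **MSE scale.** The reconstruction error is averaged over samples *and*
  features, so penalty weights keep a meaning independent of the feature
  count. The correntropy (MCC) term follows its printed form — elementwise
  Gaussian kernel `exp(-r^2 / 2 sigma^2) / (sqrt(2 pi) sigma)` summed over
  features, averaged over samples — so the RAE loss scale grows with m.
- **Swap noise** replaces each entry, independently with probability p, by
  a value drawn uniformly with replacement from the same column.
- **Contractive penalty.** The encoder Jacobian of a single dense layer is
  `diag(phi1'(a)) W`, giving the closed form
  `sum_k phi1'(a_k)^2 sum_j W_kj^2` per sample for both activations (for
  relu almost everywhere); tests verify it against central finite
  differences of the encoder.
- **KL sparsity.** `rho_hat_j` is the batch-mean activation of unit j,
  clipped to `[1e-7, 1 - 1e-7]` (relu outputs are not confined to (0,1);
  the Bernoulli analogy needs the clip), and the divergence is summed over
  units.
- **Weight decay** covers both weight matrices, not the biases.

Training: minibatch gradient descent (batch 256 by default; gradients are
hand-derived and finite-difference-tested), optimizers Adam / Adamax /
RMSprop with their standard moment constants, Glorot-uniform
initialization, up to 2000 epochs with early stopping once the validation
loss fails to improve for more than 5 consecutive epochs; the parameters
of the best validation epoch are returned. The validation split is 10% of
the training split, stratified by outcome. The DAE's corruption stream is
seeded independently of initialization and shuffling, so `swap_p = 0`
reproduces the vanilla AE epoch for epoch — a tested equivalence, along
with `lambda = 0` (CAE) and `beta = 0` (SAE).

Variant-specific hyperparameters are fixed ahead of the grid (defaults:
swap p = 0.15, lambda_CAE = 1e-4, rho = 0.05, beta = 1e-3, sigma = 1.0,
weight decay 1e-4), mirroring the study design of tuning them once at a
standard setting; all are configurable and logged.

## Retrieval and metric learning

Retrieval is exact k-NN (k in {5, 10, 15, 20}). The Mahalanobis distance
is the Euclidean distance after a learned square linear map L; the
square-root convention is used so L = I reduces to the Euclidean distance
exactly (the convention is monotone in the squared form, so neighbor sets
are unaffected). Distance ties are broken by lower training-row index; a
vote fraction of exactly 0.5 predicts the positive class (both outcomes
are rare events and F1 centers the positive class) — configurable.

Three metric learners produce L, each required by a test to score its own
objective at L no worse than at the identity initialization:

- **LMNN**: large-margin pull/push over k same-class target neighbors,
  optimized by L-BFGS on an analytic gradient via the weighted-scatter
  identity; target neighbors are fixed at the Euclidean solution.
- **NCA**: softmax leave-one-out k-NN score, backed by scikit-learn with
  identity initialization; the reported objective is recomputed by a
  direct implementation of the softmax score.
- **MLKR**: leave-one-out Nadaraya–Watson regression error; binary labels
  are treated as {0,1} regression targets, per its formulation.

## Preprocessing

In order: drop medications/procedures present in strictly fewer than 1% of
patients; drop labs with a missing rate strictly over 30%; impute the
remaining missing labs by single-chain chained equations (column-wise least
squares on all other features, mean-initialized, 10 sweeps, coefficients
frozen for held-out data); Winsorize medication and lab columns at the
1st/99th percentiles (linear-interpolation quantiles); min–max scale to
[0, 1], mapping constant columns to 0 and clipping held-out values into
[0, 1]. Binary procedure columns are exempt from Winsorizing — percentile
clamping of a 0/1 column would erase rare positives. All statistics are
fitted on the training fold only by default (`fit_scope="train_only"`); a
global mode exists. Strict idempotence of the fitted transform is not
attainable for an affine rescale; the tested contract is determinism plus
output confined to [0, 1].

## Synthetic cohorts

The study data are private EHR extracts, so every experiment runs on
synthetic cohorts with the structure the pipeline assumes. Each patient
has a latent factor vector `h ~ N(0, I_d)` (default d = 4). Outcomes are
Bernoulli with logit affine in h; the intercept is root-found on the
simulated sample so the empirical prevalence matches the target (defaults:
the cohorts' 11.90% AKI / 12.62% mortality; presets carry both sites'
counts and feature counts 277/288/14 and 328/312/14). Medications are
zero-inflated lognormal with a factor-driven logistic gate, procedures
Bernoulli with logit affine in h, labs affine in h plus Gaussian noise
with MCAR missingness at per-column rates drawn from (5%, 45%). Per-column
nonzero rates are drawn log-uniformly from (0.2%, 30%) — EHR prevalence is
heavy-tailed — with a logistic-normal intercept correction so realized
prevalence tracks the drawn rate; some columns land below the 1% filter
threshold by design. A fraction of observed numeric entries (default 1%)
is replaced by values beyond the column's 99.9th percentile.

Factor loadings (gate logit 2.0, log-dose 0.6, lab 2.0 along unit-norm
directions) and the default label signal strength (4.0) were set so that
plain k-NN on the preprocessed feature table reaches F1 ≈ 0.27 at k = 5
under the default prevalences — the regime reported for raw inpatient
snapshots — making the AE-vs-baseline comparisons informative rather than
floor effects.

What the generator does **not** emulate: longitudinal encounter structure,
informative (MNAR) missingness, feature-feature dependence beyond the
shared factors, coded-vocabulary semantics, or site effects other than
prevalence/feature-count differences. Passing tests therefore demonstrate
correctness of the machinery and qualitative orderings under a
low-rank-factor world, not performance on real EHR data.

## Experimental harness

Stratified k-fold cross-validation (default 5-fold; folds stratified on
the joint outcome code so both targets share folds). Per fold the
preprocessor is fitted on the training split only, the AE trained with its
internal validation split, both splits encoded, and retrieval scored by
F1 (positive class), AUPRC (precision–recall step integration) and AUROC,
with the k-NN positive vote fraction as the continuous score — for the
baselines too (raw preprocessed features; PCA projection keeping the
smallest component count with ≥ 99% cumulative explained variance, fitted
on the training fold). The full grid is the Cartesian product of 4 learning
rates × 3 optimizers × 7 latent ratios × 2 activations = 168 configurations
per variant; reduced axes are supported and used for desk-scale runs.

The Mahalanobis stage selects each variant's best configuration by
Euclidean F1 at k = 5 (once unconstrained, once with latent ratio fixed at
0.5), subsamples the transformed train/test splits (50%, or 70% on the
smaller site) with a seed shared across variants, learns each metric on the
subsample, and evaluates k = 5 retrieval; the same metrics are also learned
directly on the preprocessed features.

Comparison statistics: one-tailed paired t-test across configurations
(paired by configuration id, per-configuration values are fold means;
zero-variance differences use p = 0 / 0.5 / 1 by sign), top-5 mean ± SD
per variant (all configurations, flagged, when fewer than five exist), and
Spearman rank concordance of per-configuration metrics between the two
sites. The 0.01 significance threshold is reported, never used as a gate.

## Problem sizes and reproducibility

Library defaults are paper-scale (site presets of 13,752 × 579 and
9,568 × 654, the full 168-configuration grid, 5-fold CV). The analysis
scripts and the acceptance script run desk-scale versions chosen so the
whole pipeline reruns in minutes on one CPU: cohorts of 700–1,600 patients
with 80–140 features, a 2 × 1 × 2 × 1 grid, 3-fold CV, up to 150 epochs.
Every random draw descends from one master seed through named per-stage
seeds (SHA-256 of `seed:stage`, reduced below 2^31), and all training,
generation and metric learning are deterministic given their seeds.

## Known limitations

- The evaluated scores are k-NN vote fractions, so AUROC/AUPRC are
  computed on a coarse (k+1)-level score; this is shared by all methods
  compared.
- LMNN re-derives its active impostor set inside each objective
  evaluation; the objective is piecewise smooth and L-BFGS may stop at the
  iteration budget (it then returns the best iterate and warns).
- The chained-equation imputer is linear; nonlinear feature-lab
  relationships would need a richer regressor.
- Paper-scale grid runs (168 × 5 variants × 5 folds) are computationally
  heavy on one CPU; the harness supports them but the shipped scripts do
  not run them.
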