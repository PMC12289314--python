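# patsim — autoencoder representations for similar-patient retrieval

Clinicians reason from similar patients: given an inpatient's snapshot of
medications, procedures and lab results, retrieve the k most comparable
patients from a reference cohort and read outcomes off that neighborhood.
Raw EHR feature tables make this hard — high-dimensional, mixed-type,
sparse and noisy — so a common recipe is to learn a compact patient
representation with an autoencoder and run k-nearest-neighbor retrieval in
the latent space. `patsim` implements and compares that whole pipeline:

- **Five autoencoder variants** sharing one 3-layer encoder/decoder
  `Z = phi1(WX + b)`, `X' = phi2(W'Z + b')` and differing only in loss:
  vanilla (MSE), denoising (swap noise), contractive (Jacobian Frobenius
  penalty `lambda * ||J_f(X)||_F^2`), sparse (Bernoulli KL penalty
  `beta * KL(rho || rho_hat)`), and robust (negative correntropy
  `-MCC(X, X')` with KL sparsity and weight decay). Implemented in numpy
  with hand-derived, finite-difference-tested gradients and Adam / Adamax /
  RMSprop training with early stopping.
- **Retrieval**: exact k-NN with Euclidean distance or a learned
  Mahalanobis distance `d(u, v) = ||Lu - Lv||`, with L from LMNN, NCA or
  MLKR; majority-vote classification of AKI onset and 1-year mortality.
- **Preprocessing**: rare-feature and missing-lab filters, chained-equation
  imputation, Winsorizing, min–max scaling — all leakage-safe (fitted on
  training folds only).
- **Evaluation harness**: stratified cross-validation, the
  168-configuration hyperparameter grid (4 learning rates × 3 optimizers ×
  7 latent ratios × 2 activations), raw and PCA-99% baselines, F1 / AUPRC /
  AUROC, one-tailed paired t-tests, top-5 summaries, and cross-site
  Spearman concordance.
- **Synthetic cohort generator**: the study cohorts are private, so a
  latent-factor generator emulates their structure (mixed feature kinds,
  sub-1% sparsity, lab missingness around the 30% filter boundary,
  outliers, two calibrated outcome prevalences) and makes every stage
  testable end to end.

## Worked example

```python
from patsim import (CohortSpec, generate_cohort, GridSpec, run_grid)
from patsim.evaluation import ttest_matrix

spec = CohortSpec(n_patients=900, n_medications=40, n_procedures=40,
                  n_labs=10, seed=7)
table = generate_cohort(spec)              # synthetic two-outcome cohort
grid = GridSpec(learning_rates=(1e-3, 1e-2), optimizers=("adam",),
                latent_ratios=(0.15, 0.5), activations=("sigmoid",),
                variants=("AE", "DAE"), ks=(5,), n_folds=3,
                max_epochs=150, batch_size=128)
records = run_grid(table, grid)            # per-fold retrieval metrics
print(records[(records.k == 5) & (records.target == "aki")]
      .groupby("variant")["f1"].mean().round(3))
```

prints (seed 7):

```
variant
AE     0.304
DAE    0.312
pca    0.242
raw    0.243
Name: f1, dtype: float64
```

i.e. on this cohort both autoencoders beat k-NN on the raw and
PCA-projected features at k = 5, and the denoising variant leads — each
number is the mean F1 for AKI-onset prediction over 3 folds and the grid's
configurations.

The same stages run from the shell (`patsim generate | preprocess | train |
embed | retrieve | evaluate | grid | metric-experiment | compare |
report`), each writing a `manifest.json` with the resolved configuration
and every derived seed. The `analysis/` scripts are the full narrative:
`01_simulate_cohorts.py` builds two synthetic sites,
`02_grid_search.py` runs the reduced grid on both,
`03_metric_learning.py` runs the subsampled Mahalanobis protocol on each
variant's best configuration, and `04_compare.py` computes the comparison
statistics; tables land in `results/`.

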