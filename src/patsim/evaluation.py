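"""Experimental harness: stratified cross-validation, baselines, retrieval
metrics, the hyperparameter grid, the Mahalanobis subsampling protocol, and
the comparison statistics (one-tailed paired t, top-5 summaries, Spearman
rank concordance)."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import autoencoder as ae
from . import preprocess as pp
from .cohort import FeatureTable
from .metric_learning import learn_metric
from .retrieval import MetricTransform, knn_query

TARGETS = ("aki", "mortality")


@dataclass(frozen=True)
class GridSpec:
    """The hyperparameter search space; defaults give 4*3*7*2 = 168
    configurations per variant."""

    learning_rates: tuple = ae.GRID_LEARNING_RATES
    optimizers: tuple = ae.GRID_OPTIMIZERS
    latent_ratios: tuple = ae.GRID_LATENT_RATIOS
    activations: tuple = ae.GRID_ACTIVATIONS
    variants: tuple = ae.VARIANTS
    ks: tuple = (5, 10, 15, 20)
    targets: tuple = TARGETS
    n_folds: int = 5
    seed: int = 0
    max_epochs: int = 2000
    patience: int = 5
    batch_size: int = 256

    @property
    def size(self) -> int:
        """Configurations per variant."""
        return (len(self.learning_rates) * len(self.optimizers)
                * len(self.latent_ratios) * len(self.activations))

    def configs(self, variant: str) -> list[ae.AEConfig]:
        """Stable enumeration of the Cartesian product for one variant.
        Config ids are reproducible across runs."""
        out = []
        for lr, opt, ratio, act in itertools.product(
                self.learning_rates, self.optimizers, self.latent_ratios,
                self.activations):
            out.append(ae.AEConfig(
                variant=variant, learning_rate=lr, optimizer=opt,
                latent_ratio=ratio, activation=act,
                max_epochs=self.max_epochs, patience=self.patience,
                batch_size=self.batch_size, seed=self.seed))
        return out


def config_id(config: ae.AEConfig) -> str:
    return (f"lr{config.learning_rate:g}-{config.optimizer}"
            f"-r{config.latent_ratio:g}-{config.activation}")


# ---------------------------------------------------------------------------
# Folds and metrics


def stratified_kfold(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment (0..n_folds-1 per sample); per-fold class counts
    differ from exact proportionality by at most 1."""
    labels = np.asarray(labels)
    if labels.size < n_folds:
        raise ValueError("need at least one sample per fold")
    binc = np.bincount(pd.factorize(labels)[0])
    if (binc < n_folds).any():
        warnings.warn("a class has fewer members than folds; stratification "
                      "is best-effort", stacklevel=2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignment[test_idx] = fold
    return assignment


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                           scores: np.ndarray) -> dict:
    """F1 on the positive class, AUPRC (precision-recall step integration)
    and AUROC (rank statistic) on the vote-fraction scores. AUCs are NaN
    when only one class is present."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=float)
    if not (y_true.shape == y_pred.shape == scores.shape):
        raise ValueError("length mismatch")
    out = {"f1": float(f1_score(y_true, y_pred, zero_division=0.0))}
    if np.unique(y_true).size < 2:
        out["auprc"] = np.nan
        out["auroc"] = np.nan
    else:
        out["auprc"] = float(average_precision_score(y_true, scores))
        out["auroc"] = float(roc_auc_score(y_true, scores))
    return out


def pca_baseline(X_train: np.ndarray, X_test: np.ndarray,
                 variance_retained: float = 0.99
                 ) -> tuple[np.ndarray, np.ndarray, int]:
    """Project both splits onto the smallest number of train-fitted
    principal components reaching the cumulative explained-variance target."""
    pca = PCA(svd_solver="full")
    pca.fit(X_train)
    if variance_retained >= 1.0:
        ncomp = int((pca.explained_variance_ > 1e-12).sum())
    else:
        cum = np.cumsum(pca.explained_variance_ratio_)
        ncomp = int(np.searchsorted(cum, variance_retained) + 1)
    ncomp = max(1, ncomp)
    return (pca.transform(X_train)[:, :ncomp],
            pca.transform(X_test)[:, :ncomp], ncomp)


# ---------------------------------------------------------------------------
# Per-configuration evaluation


def _fold_assignment(table: FeatureTable, grid: GridSpec) -> np.ndarray:
    # shared folds for both targets: stratify on the joint outcome code
    joint = table.labels_aki * 2 + table.labels_mortality
    return stratified_kfold(joint, grid.n_folds, grid.seed)


def _retrieval_records(Z_train, Z_test, table, train_idx, test_idx, grid,
                       base: dict, metric=None) -> list[dict]:
    rows = []
    for target in grid.targets:
        y = table.labels(target)
        for k in grid.ks:
            res = knn_query(Z_train, y[train_idx], Z_test, k, metric=metric)
            m = classification_metrics(y[test_idx], res.predictions, res.scores)
            rows.append({**base, "target": target, "k": k, **m})
    return rows


def fit_fold(table: FeatureTable, config: ae.AEConfig, fold: int,
             folds: np.ndarray, pp_config: pp.PreprocessConfig | None = None
             ) -> dict:
    """Fit the per-fold pipeline state (preprocessor + AE) on the training
    split only, and encode both splits. Returned dict holds every fitted
    artifact so leakage can be audited."""
    pp_config = pp_config or pp.PreprocessConfig()
    test_idx = np.flatnonzero(folds == fold)
    train_idx = np.flatnonzero(folds != fold)
    tr, te = table.select_rows(train_idx), table.select_rows(test_idx)
    fitted = pp.fit(tr, pp_config)
    X_tr = fitted.apply(tr).values
    X_te = fitted.apply(te).values
    fit_idx, val_idx = ae.validation_split(
        X_tr, tr.labels_aki, frac=0.10, seed=config.seed + fold)
    model, trace = ae.train(X_tr[fit_idx], X_tr[val_idx],
                            replace(config, seed=config.seed + fold))
    return {"fitted": fitted, "model": model, "trace": trace,
            "train_idx": train_idx, "test_idx": test_idx,
            "X_tr": X_tr, "X_te": X_te,
            "Z_tr": ae.encode(model, X_tr), "Z_te": ae.encode(model, X_te)}


def evaluate_config(table: FeatureTable, config: ae.AEConfig, grid: GridSpec,
                    pp_config: pp.PreprocessConfig | None = None,
                    include_baselines: bool = True,
                    fold_assignment: np.ndarray | None = None) -> pd.DataFrame:
    """Cross-validated Euclidean k-NN evaluation of one AE configuration,
    optionally with raw-data and PCA-99% baselines on the same folds.

    Per fold: fit the preprocessor on the training split only, train the AE
    (with an internal stratified validation split for early stopping),
    encode both splits, then retrieve and score for every k and target.
    """
    folds = fold_assignment if fold_assignment is not None \
        else _fold_assignment(table, grid)
    cid = config_id(config)
    rows: list[dict] = []
    for fold in range(grid.n_folds):
        art = fit_fold(table, config, fold, folds, pp_config)
        train_idx, test_idx = art["train_idx"], art["test_idx"]
        X_tr, X_te = art["X_tr"], art["X_te"]
        Z_tr, Z_te = art["Z_tr"], art["Z_te"]
        base = {"variant": config.variant, "config_id": cid, "fold": fold,
                "distance": "euclidean"}
        rows += _retrieval_records(Z_tr, Z_te, table, train_idx, test_idx,
                                   grid, base)
        if include_baselines:
            rows += _retrieval_records(X_tr, X_te, table, train_idx, test_idx,
                                       grid, {"variant": "raw", "config_id": "raw",
                                              "fold": fold, "distance": "euclidean"})
            P_tr, P_te, _ = pca_baseline(X_tr, X_te)
            rows += _retrieval_records(P_tr, P_te, table, train_idx, test_idx,
                                       grid, {"variant": "pca", "config_id": "pca",
                                              "fold": fold, "distance": "euclidean"})
    return pd.DataFrame(rows)


def run_grid(table: FeatureTable, grid: GridSpec,
             pp_config: pp.PreprocessConfig | None = None,
             progress: bool = False) -> pd.DataFrame:
    """Evaluate the full Cartesian grid for every variant (baselines are
    computed once, on the shared folds)."""
    folds = _fold_assignment(table, grid)
    frames = []
    first = True
    for variant in grid.variants:
        for config in grid.configs(variant):
            if progress:
                print(f"  {variant} {config_id(config)}", flush=True)
            frames.append(evaluate_config(
                table, config, grid, pp_config,
                include_baselines=first, fold_assignment=folds))
            first = False
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Mahalanobis subsampling experiment


def mahalanobis_experiment(table: FeatureTable,
                           best_configs: dict[str, ae.AEConfig],
                           sample_fraction: float, seed: int,
                           grid: GridSpec | None = None,
                           pp_config: pp.PreprocessConfig | None = None,
                           methods: tuple = ("euclidean", "lmnn", "nca", "mlkr"),
                           k: int = 5) -> pd.DataFrame:
    """Metric-learning comparison on subsampled transformed splits.

    Per fold, the same randomly sampled row subsets (fixed by ``seed``, hence
    identical across variants) of the transformed train and test splits are
    used to learn each metric and evaluate k-NN retrieval; the metrics are
    also learned on the raw preprocessed data.
    """
    grid = grid or GridSpec()
    pp_config = pp_config or pp.PreprocessConfig()
    folds = _fold_assignment(table, grid)
    rng = np.random.default_rng(seed)
    # one draw per fold, shared across every variant
    sub_idx: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for fold in range(grid.n_folds):
        n_te = int((folds == fold).sum())
        n_tr = int((folds != fold).sum())
        s_tr = np.sort(rng.choice(n_tr, size=max(1, int(round(sample_fraction * n_tr))),
                                  replace=False))
        s_te = np.sort(rng.choice(n_te, size=max(1, int(round(sample_fraction * n_te))),
                                  replace=False))
        if s_tr.size < k:
            raise ValueError("subsample smaller than the neighborhood size k")
        sub_idx[fold] = (s_tr, s_te)

    rows: list[dict] = []

    def eval_block(Z_tr, Z_te, y_tr, y_te, variant, cid, fold, target):
        for method in methods:
            if method == "euclidean":
                metric = None
            else:
                try:
                    metric = learn_metric(Z_tr, y_tr, method, k=k, seed=seed)
                except ValueError as exc:
                    warnings.warn(f"{method} failed on {variant}/{target}: {exc}",
                                  stacklevel=2)
                    continue
            res = knn_query(Z_tr, y_tr, Z_te, k, metric=metric)
            m = classification_metrics(y_te, res.predictions, res.scores)
            rows.append({"variant": variant, "config_id": cid, "fold": fold,
                         "distance": method, "target": target, "k": k, **m})

    for fold in range(grid.n_folds):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        tr, te = table.select_rows(train_idx), table.select_rows(test_idx)
        fitted = pp.fit(tr, pp_config)
        X_tr = fitted.apply(tr).values
        X_te = fitted.apply(te).values
        s_tr, s_te = sub_idx[fold]

        for target in grid.targets:
            y = table.labels(target)
            y_tr = y[train_idx][s_tr]
            y_te = y[test_idx][s_te]
            eval_block(X_tr[s_tr], X_te[s_te], y_tr, y_te, "raw", "raw",
                       fold, target)
            for variant, config in best_configs.items():
                fit_idx, val_idx = ae.validation_split(
                    X_tr, tr.labels_aki, frac=0.10, seed=config.seed + fold)
                model, _ = ae.train(X_tr[fit_idx], X_tr[val_idx],
                                    replace(config, seed=config.seed + fold))
                Z_tr = ae.encode(model, X_tr)[s_tr]
                Z_te = ae.encode(model, X_te)[s_te]
                eval_block(Z_tr, Z_te, y_tr, y_te, variant, config_id(config),
                           fold, target)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Comparison statistics


def paired_ttest_onetailed(a: np.ndarray, b: np.ndarray) -> float:
    """One-tailed paired t-test of mean(a - b) > 0, paired by configuration.

    Zero-variance differences use the convention p=0 if mean > 0, p=1 if
    mean < 0, p=0.5 if all differences are zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least two paired observations")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        mean = d.mean()
        return 0.0 if mean > 0 else (1.0 if mean < 0 else 0.5)
    t = d.mean() / (sd / np.sqrt(d.size))
    return float(stats.t.sf(t, df=d.size - 1))


def ttest_matrix(records: pd.DataFrame, metric: str = "f1",
                 target: str = "aki", k: int = 5,
                 variants: tuple = ae.VARIANTS) -> pd.DataFrame:
    """Pairwise one-tailed p-values: entry (row, col) tests whether the row
    variant outperforms the column variant across configurations (per-config
    values are fold means)."""
    sub = records[(records["target"] == target) & (records["k"] == k)
                  & records["variant"].isin(variants)]
    per_config = (sub.groupby(["variant", "config_id"])[metric]
                  .mean().unstack("config_id"))
    out = pd.DataFrame(np.nan, index=list(variants), columns=list(variants))
    for va in variants:
        for vb in variants:
            if va == vb:
                continue
            a, b = per_config.loc[va], per_config.loc[vb]
            mask = a.notna() & b.notna()
            out.loc[va, vb] = paired_ttest_onetailed(a[mask].to_numpy(),
                                                     b[mask].to_numpy())
    return out


def top5_summary(records: pd.DataFrame, metric: str = "f1",
                 n_top: int = 5) -> pd.DataFrame:
    """Mean and SD of each variant's ``n_top`` best configurations (ranked
    by fold-mean metric; ties broken by config id), per target and k."""
    rows = []
    for (variant, target, k), sub in records.groupby(["variant", "target", "k"]):
        per_config = (sub.groupby("config_id")[metric].mean()
                      .reset_index()
                      .sort_values([metric, "config_id"],
                                   ascending=[False, True]))
        n_avail = len(per_config)
        if n_avail < n_top:
            warnings.warn(f"{variant}/{target}/k={k}: only {n_avail} "
                          f"configurations available for a top-{n_top} summary",
                          stacklevel=2)
        top = per_config.head(n_top)[metric]
        rows.append({"variant": variant, "target": target, "k": k,
                     "n_configs": int(min(n_top, n_avail)),
                     "mean": float(top.mean()),
                     "sd": float(top.std(ddof=1)) if len(top) > 1 else 0.0})
    return pd.DataFrame(rows)


def select_best_configs(records: pd.DataFrame, grid: GridSpec,
                        metric: str = "f1", target: str = "aki", k: int = 5,
                        latent_ratio: float | None = None
                        ) -> dict[str, ae.AEConfig]:
    """Per variant, the configuration with the highest fold-mean metric at
    Euclidean k-NN (optionally restricted to one latent ratio, for the
    dimension-controlled comparison)."""
    sub = records[(records["target"] == target) & (records["k"] == k)
                  & (records["distance"] == "euclidean")
                  & records["variant"].isin(grid.variants)]
    best: dict[str, ae.AEConfig] = {}
    for variant in grid.variants:
        candidates = {config_id(c): c for c in grid.configs(variant)
                      if latent_ratio is None or c.latent_ratio == latent_ratio}
        vsub = sub[(sub["variant"] == variant)
                   & sub["config_id"].isin(candidates)]
        if vsub.empty:
            continue
        means = (vsub.groupby("config_id")[metric].mean()
                 .sort_values(ascending=False))
        best[variant] = candidates[means.index[0]]
    return best


def site_concordance(records1: pd.DataFrame, records2: pd.DataFrame,
                     metric: str = "f1", target: str = "aki", k: int = 5
                     ) -> float:
    """Spearman rho between two sites' per-configuration fold-mean metrics,
    paired by (variant, config id)."""
    def per_config(r):
        sub = r[(r["target"] == target) & (r["k"] == k)
                & r["variant"].isin(ae.VARIANTS)]
        return sub.groupby(["variant", "config_id"])[metric].mean()

    a, b = per_config(records1), per_config(records2)
    joined = pd.concat([a.rename("a"), b.rename("b")], axis=1, join="inner")
    return spearman_concordance(joined["a"].to_numpy(), joined["b"].to_numpy())


def spearman_concordance(metrics_site1: np.ndarray,
                         metrics_site2: np.ndarray) -> float:
    """Spearman rho between two sites' per-configuration metrics (Pearson on
    average ranks). NaN, with a warning, for constant input."""
    a = np.asarray(metrics_site1, dtype=float)
    b = np.asarray(metrics_site2, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)
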