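"""Feature-table processing chain.

Order of operations: drop medications/procedures recorded in fewer than 1% of
patients, drop labs with a missing rate over 30%, fill the remaining missing
lab values by chained-equation imputation, Winsorize continuous columns at
the 1%/99% percentiles, then min-max scale every column to [0, 1].

All statistics can be fitted on a training split only (``fit_scope=
"train_only"``, the default) and replayed on held-out data, or fitted
globally.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import FeatureTable, LAB, MEDICATION, PROCEDURE

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    rare_threshold: float = 0.01
    lab_missing_threshold: float = 0.30
    winsor_tail: float = 0.01
    impute_iterations: int = 10
    fit_scope: str = "train_only"  # or "global"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rare_threshold", "lab_missing_threshold", "winsor_tail"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if self.impute_iterations < 1:
            raise ValueError("impute_iterations must be >= 1")
        if self.fit_scope not in ("train_only", "global"):
            raise ValueError("fit_scope must be 'train_only' or 'global'")


# ---------------------------------------------------------------------------
# Column filters


def column_prevalence(table: FeatureTable) -> np.ndarray:
    """Fraction of patients with a positive recorded value, per column."""
    obs = np.isfinite(table.values)
    with np.errstate(invalid="ignore"):
        positive = obs & (table.values > 0)
    return positive.sum(axis=0) / table.n


def filter_rare_features(table: FeatureTable, threshold: float = 0.01) -> FeatureTable:
    """Drop medication/procedure columns present in strictly fewer than
    ``threshold`` of patients. Lab columns are never dropped by this rule."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    filterable = np.isin(table.feature_kinds, (MEDICATION, PROCEDURE))
    if not filterable.any():
        warnings.warn("no medication or procedure columns to filter", stacklevel=2)
        return table.select_columns(np.arange(table.m))
    prev = column_prevalence(table)
    keep = ~filterable | (prev >= threshold)
    return table.select_columns(np.flatnonzero(keep))


def filter_missing_labs(table: FeatureTable, threshold: float = 0.30) -> FeatureTable:
    """Drop lab columns whose missing fraction is strictly greater than
    ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    missing = np.isnan(table.values).mean(axis=0)
    keep = (table.feature_kinds != LAB) | (missing <= threshold)
    return table.select_columns(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Chained-equation imputation


@dataclass
class ChainedImputer:
    """Single-imputation chained equations for lab columns.

    Missing entries are initialized at the fitted column means, then each lab
    column with missing data is regressed (ordinary least squares with
    intercept) on every other column, sweeping the columns in order for a
    fixed number of iterations. The coefficients from the final sweep are
    stored so held-out data can be imputed by replaying the same sweeps.
    Observed entries are never modified.
    """

    iterations: int = 10
    lab_cols: list[int] = field(default_factory=list)
    means: np.ndarray | None = None
    coefs: dict[int, np.ndarray] = field(default_factory=dict)  # col -> [intercept, betas]

    def fit(self, values: np.ndarray, lab_cols: np.ndarray,
            col_names: list[str]) -> "ChainedImputer":
        X = values.copy()
        n, m = X.shape
        for c in lab_cols:
            if np.isnan(X[:, c]).all():
                raise ValueError(f"lab column {col_names[c]!r} has no observed values")
        self.means = np.nanmean(X, axis=0)
        # Coefficients are fitted for every lab column (not just those with
        # missing data here) so held-out tables can be imputed regardless of
        # which labs happen to be missing in them.
        self.lab_cols = [int(c) for c in lab_cols]
        miss = {c: np.isnan(X[:, c]) for c in self.lab_cols}
        for c in self.lab_cols:
            X[miss[c], c] = self.means[c]
        for _ in range(self.iterations):
            for c in self.lab_cols:
                other = np.delete(np.arange(m), c)
                A = np.column_stack([np.ones(n), X[:, other]])
                obs = ~miss[c]
                beta, *_ = np.linalg.lstsq(A[obs], X[obs, c], rcond=None)
                X[miss[c], c] = A[miss[c]] @ beta
                self.coefs[c] = beta
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        X = values.copy()
        n, m = X.shape
        miss = {c: np.isnan(X[:, c]) for c in self.lab_cols}
        if np.isnan(np.delete(X, self.lab_cols, axis=1)).any():
            raise ValueError("missing values outside the fitted lab columns")
        for c in self.lab_cols:
            X[miss[c], c] = self.means[c]
        for _ in range(self.iterations):
            for c in self.lab_cols:
                if not miss[c].any():
                    continue
                other = np.delete(np.arange(m), c)
                A = np.column_stack([np.ones(miss[c].sum()), X[miss[c]][:, other]])
                X[miss[c], c] = A @ self.coefs[c]
        return X


def impute_chained(table: FeatureTable, config: PreprocessConfig) -> FeatureTable:
    """Fill missing lab entries in place of NaN; observed entries untouched."""
    imputer = ChainedImputer(iterations=config.impute_iterations)
    imputer.fit(table.values, table.columns_of_kind(LAB), table.feature_names)
    out = table.select_columns(np.arange(table.m))
    out.values = imputer.transform(table.values)
    return out


# ---------------------------------------------------------------------------
# Winsorizing and min-max scaling


def winsor_limits(values: np.ndarray, tail: float) -> tuple[float, float]:
    """Empirical tail/(1-tail) quantiles (linear interpolation of order
    statistics)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty column")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values in column")
    return float(np.quantile(v, tail)), float(np.quantile(v, 1.0 - tail))


def winsorize_fit_apply(values: np.ndarray, tail: float = 0.01) -> np.ndarray:
    lo, hi = winsor_limits(values, tail)
    return np.clip(np.asarray(values, dtype=float), lo, hi)


def minmax_fit_apply(values: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); constant columns map to 0 by convention."""
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("non-finite values in column")
    mn, mx = v.min(), v.max()
    if mx == mn:
        return np.zeros_like(v)
    return (v - mn) / (mx - mn)


# ---------------------------------------------------------------------------
# Fitted pipeline


@dataclass
class FittedPreprocessor:
    """Frozen preprocessing statistics, replayable on held-out tables.

    ``apply`` performs, in order: column selection, imputation, Winsorize
    clamp to the stored limits, min-max rescale with the stored min/max, and
    a final clip to [0, 1] (held-out values may fall outside the fitted
    range).
    """

    config: PreprocessConfig
    kept_names: list[str]
    kept_kinds: np.ndarray
    winsor_lo: np.ndarray  # NaN where Winsorizing does not apply (procedures)
    winsor_hi: np.ndarray
    col_min: np.ndarray
    col_max: np.ndarray
    imputer: ChainedImputer

    def apply(self, table: FeatureTable) -> FeatureTable:
        name_to_idx = {n: i for i, n in enumerate(table.feature_names)}
        missing = [n for n in self.kept_names if n not in name_to_idx]
        if missing:
            raise KeyError(f"table lacks fitted columns: {missing[:5]}")
        sub = table.select_columns(np.array([name_to_idx[n] for n in self.kept_names]))
        X = self.imputer.transform(sub.values)
        lo = np.where(np.isnan(self.winsor_lo), -np.inf, self.winsor_lo)
        hi = np.where(np.isnan(self.winsor_hi), np.inf, self.winsor_hi)
        X = np.clip(X, lo, hi)
        span = self.col_max - self.col_min
        safe = np.where(span > 0, span, 1.0)
        X = (X - self.col_min) / safe
        X[:, span <= 0] = 0.0
        sub.values = np.clip(X, 0.0, 1.0)
        return sub

    # JSON round trip -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "config": {
                "rare_threshold": self.config.rare_threshold,
                "lab_missing_threshold": self.config.lab_missing_threshold,
                "winsor_tail": self.config.winsor_tail,
                "impute_iterations": self.config.impute_iterations,
                "fit_scope": self.config.fit_scope,
                "seed": self.config.seed,
            },
            "kept_names": self.kept_names,
            "kept_kinds": [str(k) for k in self.kept_kinds],
            "winsor_lo": self.winsor_lo.tolist(),
            "winsor_hi": self.winsor_hi.tolist(),
            "col_min": self.col_min.tolist(),
            "col_max": self.col_max.tolist(),
            "imputer": {
                "iterations": self.imputer.iterations,
                "lab_cols": self.imputer.lab_cols,
                "means": self.imputer.means.tolist(),
                "coefs": {str(c): b.tolist() for c, b in self.imputer.coefs.items()},
            },
        })

    @classmethod
    def from_json(cls, text: str) -> "FittedPreprocessor":
        d = json.loads(text)
        imp = ChainedImputer(
            iterations=d["imputer"]["iterations"],
            lab_cols=[int(c) for c in d["imputer"]["lab_cols"]],
            means=np.array(d["imputer"]["means"]),
            coefs={int(c): np.array(b) for c, b in d["imputer"]["coefs"].items()},
        )
        return cls(
            config=PreprocessConfig(**d["config"]),
            kept_names=d["kept_names"],
            kept_kinds=np.array(d["kept_kinds"], dtype=object),
            winsor_lo=np.array(d["winsor_lo"]),
            winsor_hi=np.array(d["winsor_hi"]),
            col_min=np.array(d["col_min"]),
            col_max=np.array(d["col_max"]),
            imputer=imp,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "FittedPreprocessor":
        return cls.from_json(Path(path).read_text())


def fit(table: FeatureTable, config: PreprocessConfig | None = None) -> FittedPreprocessor:
    """Fit all preprocessing statistics on ``table`` (the training split when
    ``fit_scope='train_only'``)."""
    config = config or PreprocessConfig()
    kept = filter_missing_labs(
        filter_rare_features(table, config.rare_threshold),
        config.lab_missing_threshold,
    )
    imputer = ChainedImputer(iterations=config.impute_iterations)
    imputer.fit(kept.values, kept.columns_of_kind(LAB), kept.feature_names)
    X = imputer.transform(kept.values)

    m = X.shape[1]
    winsor_lo = np.full(m, np.nan)
    winsor_hi = np.full(m, np.nan)
    # Winsorizing targets magnitude outliers; binary procedure columns are
    # exempt (clamping 0/1 data at percentiles would erase rare positives).
    for j in range(m):
        if kept.feature_kinds[j] in (MEDICATION, LAB):
            winsor_lo[j], winsor_hi[j] = winsor_limits(X[:, j], config.winsor_tail)
            X[:, j] = np.clip(X[:, j], winsor_lo[j], winsor_hi[j])
    return FittedPreprocessor(
        config=config,
        kept_names=list(kept.feature_names),
        kept_kinds=kept.feature_kinds.copy(),
        winsor_lo=winsor_lo,
        winsor_hi=winsor_hi,
        col_min=X.min(axis=0),
        col_max=X.max(axis=0),
        imputer=imputer,
    )


def apply(fitted: FittedPreprocessor, table: FeatureTable) -> FeatureTable:
    return fitted.apply(table)


def fit_apply(table: FeatureTable, config: PreprocessConfig | None = None
              ) -> tuple[FittedPreprocessor, FeatureTable]:
    fitted = fit(table, config)
    return fitted, fitted.apply(table)
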