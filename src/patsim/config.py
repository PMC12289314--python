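"""Declarative run configuration, seed derivation, and run manifests.

Config files are YAML with up to four sections — ``cohort``, ``preprocess``,
``grid`` and ``ae`` — whose keys mirror the corresponding dataclasses.
Unknown keys are rejected (never silently ignored), values are validated,
and grid axes are restricted to the values of the hyperparameter study.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import autoencoder as ae
from .cohort import CohortSpec
from .evaluation import GridSpec
from .preprocess import PreprocessConfig

_GRID_ALLOWED = {
    "learning_rates": set(ae.GRID_LEARNING_RATES),
    "optimizers": set(ae.GRID_OPTIMIZERS),
    "latent_ratios": set(ae.GRID_LATENT_RATIOS),
    "activations": set(ae.GRID_ACTIVATIONS),
    "variants": set(ae.VARIANTS),
}

_SECTIONS = {
    "cohort": {"n_patients", "n_medications", "n_procedures", "n_labs",
               "latent_dim_true", "prevalence_aki", "prevalence_mortality",
               "label_signal_strength", "feature_sparsity_range",
               "lab_missing_rate_range", "outlier_rate", "noise_sd", "seed"},
    "preprocess": {"rare_threshold", "lab_missing_threshold", "winsor_tail",
                   "impute_iterations", "fit_scope", "seed"},
    "grid": {"learning_rates", "optimizers", "latent_ratios", "activations",
             "variants", "ks", "targets", "n_folds", "seed", "max_epochs",
             "patience", "batch_size"},
    "ae": {"variant", "learning_rate", "optimizer", "latent_ratio",
           "activation", "swap_p", "lambda_cae", "rho_sparsity",
           "beta_sparsity", "sigma_mcc", "lambda_decay", "max_epochs",
           "patience", "batch_size", "seed"},
}


class ConfigError(ValueError):
    pass


def derive_seed(master: int, stage: str) -> int:
    """Expand one global seed into a deterministic per-stage seed (< 2^31)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _check_keys(raw: dict) -> list[str]:
    problems = []
    for section, content in raw.items():
        if section not in _SECTIONS:
            problems.append(f"unknown section {section!r}")
            continue
        if content is None:
            continue
        if not isinstance(content, dict):
            problems.append(f"section {section!r} must be a mapping")
            continue
        for key in content:
            if key not in _SECTIONS[section]:
                problems.append(f"unknown key {section}.{key}")
    return problems


def _check_grid_values(grid_kw: dict) -> list[str]:
    problems = []
    for axis, allowed in _GRID_ALLOWED.items():
        if axis in grid_kw:
            bad = [v for v in grid_kw[axis] if v not in allowed]
            if bad:
                problems.append(
                    f"grid.{axis}: invalid value(s) {bad}; allowed values are "
                    f"{sorted(allowed, key=str)}")
    return problems


@dataclass
class ResolvedConfig:
    cohort: dict = field(default_factory=dict)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    ae: ae.AEConfig = field(default_factory=ae.AEConfig)

    def cohort_spec(self, **overrides) -> CohortSpec:
        kw = dict(self.cohort)
        kw.update(overrides)
        return CohortSpec(**kw)


def load_config(path: str | Path | None) -> ResolvedConfig:
    """Read and validate a YAML config; missing sections and keys fall back
    to the documented defaults (the full study grid, standard thresholds).
    An empty file resolves to the complete default configuration."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping of sections")

    problems = _check_keys(raw)
    grid_kw = dict(raw.get("grid") or {})
    for axis in ("learning_rates", "optimizers", "latent_ratios",
                 "activations", "variants", "ks", "targets"):
        if axis in grid_kw:
            grid_kw[axis] = tuple(grid_kw[axis])
    problems += _check_grid_values(grid_kw)
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))

    cohort_kw = dict(raw.get("cohort") or {})
    for key in ("feature_sparsity_range", "lab_missing_rate_range"):
        if key in cohort_kw:
            cohort_kw[key] = tuple(cohort_kw[key])
    try:
        resolved = ResolvedConfig(
            cohort=cohort_kw,
            preprocess=PreprocessConfig(**(raw.get("preprocess") or {})),
            grid=GridSpec(**grid_kw),
            ae=ae.AEConfig(**(raw.get("ae") or {})),
        )
        if "n_patients" in cohort_kw:
            resolved.cohort_spec()  # validate eagerly when complete
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    return resolved


@dataclass
class RunManifest:
    """Provenance record emitted by every CLI run: resolved configuration,
    all seeds, paths, stage timings and warnings."""

    command: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                manifest.timings[name] = round(time.perf_counter() - self.t0, 4)

        return _Timer()

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "manifest.json"
        payload = asdict(self)
        path.write_text(json.dumps(payload, indent=1, default=str))
        return path


def manifest_for(command: str, resolved: ResolvedConfig, seed: int) -> RunManifest:
    return RunManifest(
        command=command,
        config={
            "cohort": resolved.cohort,
            "preprocess": asdict(resolved.preprocess),
            "grid": asdict(resolved.grid),
            "ae": asdict(resolved.ae),
        },
        seeds={"master": seed,
               **{s: derive_seed(seed, s)
                  for s in ("cohort", "folds", "train", "metric")}},
    )
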