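"""End-to-end workflow: prepare → select → evaluate → diagnose → report.

``run_pipeline`` executes the full modeling workflow for one property series
and one method (MLR, SVR or GPR), writing reproducible JSON/CSV artifacts:

1.  load a series + descriptor matrix (delimited text) or generate a
    synthetic planted data set;
2.  prune (missing / constant / collinear columns), standardize, and build
    the deterministic every-tenth-cation folds;
3.  select descriptors — OMP with the expulsion search for MLR, greedy
    substitution selection for SVR/GPR — growing the model size while an
    extra descriptor corrects at least 20 % of the cv error;
4.  for SVR, tune (C, ε, γ) over the predetermined grid on the concluded
    descriptor set; for GPR, optimize kernel hyperparameters with restarts;
5.  cross-validate the final model, compute permutation importances, and
    (for MLR) the influence/applicability-domain table.

Every artifact carries the config hash and seed; a rerun with an identical
config reproduces identical JSON artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag
from .evaluation import cross_validate, cv_r2, permutation_importance
from .io import DescriptorMatrix, read_series
from .kernels import (
    DEFAULT_SVR_GRID,
    GprEstimator,
    HyperparamGrid,
    SvrEstimator,
    fit_gpr,
    fit_svr,
    greedy_substitution_select,
    tune_svr,
)
from .linear import _FixedSetOls, choose_model_size, expulsion_search, fit_ols
from .preprocess import assign_folds, prune_descriptors, standardize
from .synthetic import SyntheticSpec, inject_anomalies, make_planted_linear

log = logging.getLogger("ilqspr")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "prepare_inputs",
    "evaluate_model_json",
    "diagnose_model_json",
]

# fixed offsets deriving per-stage seeds from the top-level seed
_SEED_GPR = 202
_SEED_PERMUTATION = 303


@dataclass
class PipelineConfig:
    """Structured configuration of one pipeline run."""

    seed: int
    method: str = "mlr"  # mlr | svr | gpr
    series_path: str | None = None
    descriptors_path: str | None = None
    synthetic: dict | None = None  # SyntheticSpec fields (seed filled from run seed)
    solute: str = "unknown"
    n_folds: int = 10
    collinearity_threshold: float = 0.95
    corr_threshold: float = 0.4
    improvement_fraction: float = 0.20
    k_max: int = 5
    svr_grid: dict | None = None  # {"C": [...], "epsilon": [...], "gamma": [...]}
    gpr_n_restarts: int = 5
    permutation_repeats: int = 30
    outdir: str = "ilqspr_run"

    def __post_init__(self) -> None:
        if self.method not in ("mlr", "svr", "gpr"):
            raise ValueError(f"method must be mlr|svr|gpr, got {self.method!r}")
        if not 0.0 < self.collinearity_threshold <= 1.0:
            raise ValueError("collinearity_threshold out of (0, 1]")
        if not 0.0 <= self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold out of [0, 1]")
        if not 0.0 < self.improvement_fraction < 1.0:
            raise ValueError("improvement_fraction out of (0, 1)")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        has_files = self.series_path is not None and self.descriptors_path is not None
        if not has_files and self.synthetic is None:
            raise ValueError(
                "provide series_path+descriptors_path or a synthetic block"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def to_canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()[:16]

    def grid(self) -> HyperparamGrid:
        if self.svr_grid is None:
            return DEFAULT_SVR_GRID
        return HyperparamGrid(
            C_values=tuple(self.svr_grid["C"]),
            epsilon_values=tuple(self.svr_grid["epsilon"]),
            gamma_values=tuple(self.svr_grid["gamma"]),
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    descriptor_names: list[str]
    model: object
    fold_stats: object
    importance: object
    influence: object | None
    removal_log: list
    artifacts: dict[str, Path] = field(default_factory=dict)


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        spec_fields = dict(config.synthetic)
        spec_fields.setdefault("seed", config.seed)
        if "beta_true" in spec_fields:
            spec_fields["beta_true"] = tuple(spec_fields["beta_true"])
        spec = SyntheticSpec(**spec_fields)
        matrix, y, truth = make_planted_linear(spec)
        matrix, y, truth = inject_anomalies(matrix, y, truth, spec)
        log.info("generated synthetic data n=%d p=%d", matrix.n, matrix.p)
        return matrix, y, truth
    series = read_series(config.series_path, solute=config.solute)
    matrix = DescriptorMatrix.from_csv(config.descriptors_path)
    if matrix.row_ids != series.ids:
        raise ValueError("descriptor matrix rows do not match the series ids")
    return matrix, series.y, None


def _select_mlr(X, y, folds, names, config: PipelineConfig):
    traces = {}

    def builder(k: int):
        model, trace = expulsion_search(
            X, y, folds, k,
            corr_threshold=config.corr_threshold, descriptor_names=names,
        )
        traces[k] = trace
        err = 1.0 - trace.rounds[trace.best_round].cv_r2
        return model, err

    model, k = choose_model_size(
        builder, config.k_max, improvement_fraction=config.improvement_fraction
    )
    log.info("MLR selected k=%d: %s", k, model.descriptor_names)
    return model, {"k": k, "trace": traces[k]}


def _kernel_score_fn(X, y, folds, names, estimator_factory):
    index = {d: j for j, d in enumerate(names)}
    cache: dict[frozenset, float] = {}  # shared across model sizes

    def score(subset: tuple[str, ...]) -> float:
        key = frozenset(subset)
        if key not in cache:
            cols = [index[d] for d in subset]
            cache[key] = cv_r2(estimator_factory, X[:, cols], y, folds)
        return cache[key]

    return score


def _select_kernel(X, y, folds, names, config: PipelineConfig):
    if config.method == "svr":
        factory = lambda: SvrEstimator()  # defaults during selection
    else:
        factory = lambda: GprEstimator(
            optimize=True, n_restarts=0, seed=config.seed + _SEED_GPR
        )
    score = _kernel_score_fn(X, y, folds, names, factory)

    def builder(k: int):
        subset, cv = greedy_substitution_select(score, names, k)
        return subset, 1.0 - cv

    subset, k = choose_model_size(
        builder, config.k_max, improvement_fraction=config.improvement_fraction
    )
    log.info("%s selected k=%d: %s", config.method.upper(), k, subset)
    return list(subset), k


def prepare_inputs(config: PipelineConfig):
    """Load (or generate), prune, standardize and fold the inputs."""
    matrix, y, truth = _load_inputs(config)
    pruned, removed = prune_descriptors(
        matrix, collinearity_threshold=config.collinearity_threshold
    )
    std = standardize(pruned)
    folds = assign_folds(y, n_folds=config.n_folds)
    return std, y, folds, removed, truth


def _estimator_from_model_doc(config: PipelineConfig, doc: dict):
    """Rebuild the CV estimator factory a full run would have used."""
    model_type = doc["model_type"]
    if model_type == "linear":
        return lambda: _FixedSetOls(list(doc["descriptor_names"]))
    if model_type == "svr":
        hyper = doc["hyperparameters"]
        return lambda: SvrEstimator(
            C=hyper["C"], epsilon=hyper["epsilon"], gamma=hyper["gamma"]
        )
    if model_type == "gpr":
        return lambda: GprEstimator(
            optimize=True, n_restarts=config.gpr_n_restarts,
            seed=config.seed + _SEED_GPR,
        )
    raise ValueError(f"unknown model_type {model_type!r}")


def evaluate_model_json(config: PipelineConfig, model_json_path):
    """Partial rerun: the evaluation section of a full run, from a stored model."""
    doc = json.loads(Path(model_json_path).read_text())
    std, y, folds, _, _ = prepare_inputs(config)
    cols = [std.descriptor_names.index(d) for d in doc["descriptor_names"]]
    return cross_validate(
        _estimator_from_model_doc(config, doc), std.values[:, cols], y, folds
    )


def diagnose_model_json(config: PipelineConfig, model_json_path):
    """Influence diagnostics of a stored linear model on the prepared data."""
    from .linear import LinearModel

    doc = json.loads(Path(model_json_path).read_text())
    if doc["model_type"] != "linear":
        raise ValueError("influence diagnostics apply to linear models only")
    model = LinearModel.from_json(json.dumps(doc))
    std, y, _, _, _ = prepare_inputs(config)
    cols = [std.descriptor_names.index(d) for d in model.descriptor_names]
    return diag.influence_table(model, std.values[:, cols], y, ids=std.row_ids)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages for one series/method; write and return artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    std, y, folds, removed, truth = prepare_inputs(config)
    X = std.values
    names = list(std.descriptor_names)
    log.info(
        "prepared %d observations x %d descriptors (%d pruned), %d folds",
        std.n, std.p, len(removed), folds.n_folds,
    )

    influence = None
    if config.method == "mlr":
        model, select_info = _select_mlr(X, y, folds, names, config)
        cols = [names.index(d) for d in model.descriptor_names]
        Xm = X[:, cols]
        final_estimator = lambda: _FixedSetOls(list(model.descriptor_names))
        fitted = model
        influence = diag.influence_table(model, Xm, y, ids=std.row_ids)
        hyper = {}
    elif config.method == "svr":
        subset, k = _select_kernel(X, y, folds, names, config)
        cols = [names.index(d) for d in subset]
        Xm = X[:, cols]
        C, eps, gamma = tune_svr(Xm, y, folds, grid=config.grid())
        fitted = fit_svr(Xm, y, C=C, epsilon=eps, gamma=gamma, descriptor_names=subset)
        final_estimator = lambda: SvrEstimator(C=C, epsilon=eps, gamma=gamma)
        hyper = {"C": C, "epsilon": eps, "gamma": gamma}
        log.info("SVR tuned: C=%s epsilon=%s gamma=%s", C, eps, gamma)
    else:  # gpr
        subset, k = _select_kernel(X, y, folds, names, config)
        cols = [names.index(d) for d in subset]
        Xm = X[:, cols]
        fitted = fit_gpr(
            Xm, y, optimize=True, n_restarts=config.gpr_n_restarts,
            seed=config.seed + _SEED_GPR, descriptor_names=subset,
        )
        final_estimator = lambda: GprEstimator(
            optimize=True, n_restarts=config.gpr_n_restarts,
            seed=config.seed + _SEED_GPR,
        )
        hyper = fitted.kernel_params
        log.info("GPR kernel params: %s", hyper)

    stats = cross_validate(final_estimator, Xm, y, folds)
    importance = permutation_importance(
        fitted, Xm, y, list(fitted.descriptor_names),
        n_repeats=config.permutation_repeats,
        seed=config.seed + _SEED_PERMUTATION,
    )

    artifacts = _write_artifacts(
        outdir, config, std, y, folds, fitted, hyper, stats, importance,
        influence, removed, truth,
    )
    return PipelineResult(
        config=config,
        descriptor_names=list(fitted.descriptor_names),
        model=fitted,
        fold_stats=stats,
        importance=importance,
        influence=influence,
        removal_log=removed,
        artifacts=artifacts,
    )


def _write_artifacts(
    outdir, config, std, y, folds, fitted, hyper, stats, importance,
    influence, removed, truth,
):
    stamp = {"config_hash": config.config_hash, "seed": config.seed}
    paths: dict[str, Path] = {}

    def dump(name: str, payload: dict) -> None:
        path = outdir / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        paths[name.split(".")[0]] = path

    if hasattr(fitted, "to_json"):
        doc = json.loads(fitted.to_json())
    else:
        doc = {"descriptor_names": list(fitted.descriptor_names)}
    cols = [std.descriptor_names.index(d) for d in fitted.descriptor_names]
    doc.update(
        {
            "standardization": {
                "means": std.column_means[cols].tolist(),
                "sds": std.column_sds[cols].tolist(),
            },
            "hyperparameters": hyper,
            **stamp,
        }
    )
    dump("model.json", doc)
    dump("fold_stats.json", {**stats.to_dict(), **stamp})
    dump("importance.json", {**importance.to_dict(), **stamp})
    dump(
        "run.json",
        {
            "config": json.loads(config.to_canonical_json()),
            "truth": truth.to_dict() if truth is not None else None,
            "fold_sizes": folds.fold_sizes(),
            **stamp,
        },
    )

    removal = pd.DataFrame(
        [{"name": r.name, "reason": r.reason, "detail": r.detail} for r in removed]
    )
    removal.to_csv(outdir / "removed_descriptors.csv", index=False)
    paths["removed_descriptors"] = outdir / "removed_descriptors.csv"

    Xm = std.values[:, cols]
    scatter = pd.DataFrame(
        {
            "id": std.row_ids,
            "y_experimental": y,
            "y_predicted_train": np.asarray(fitted.predict(Xm), dtype=float),
            "y_predicted_oof": stats.oof_predictions,
            "fold": folds.fold_of,
        }
    )
    scatter.to_csv(outdir / "predictions.csv", index=False)
    paths["predictions"] = outdir / "predictions.csv"

    if influence is not None:
        influence.to_frame().to_csv(outdir / "influence.csv", index=False)
        paths["influence"] = outdir / "influence.csv"
        report = diag.influence_report(influence)
        report["scatter"].to_csv(outdir / "influence_plot.csv", index=False)
        paths["influence_plot"] = outdir / "influence_plot.csv"
        dump(
            "influence.json",
            {
                **{k: v for k, v in report.items() if k != "scatter"},
                **stamp,
            },
        )
    return paths
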