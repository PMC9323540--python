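"""Scoring, the 10-fold cross-validation harness, and permutation importance.

Metrics follow the conventions used throughout gas–ionic-liquid QSPR work:

* r² = 1 − SS_res/SS_tot (coefficient of determination; can be negative),
* RMSE = sqrt(mean squared error),
* CCC = Lin's concordance correlation coefficient,
  2·cov(y,ŷ) / (var(y) + var(ŷ) + (ȳ − ŷ̄)²), with the n-denominator
  (population) convention used consistently in numerator and denominator so
  the statistic is scale-consistent.

Cross-validation statistics are reported both as unweighted means over the
per-fold values ("fold_mean", the headline mode) and as pooled out-of-fold
statistics ("pooled"); the two disagree slightly whenever folds differ in
response spread, so both are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .preprocess import FoldAssignment

__all__ = [
    "Estimator",
    "FoldRecord",
    "FoldStats",
    "ImportanceTable",
    "r2",
    "rmse",
    "ccc",
    "cross_validate",
    "cv_r2",
    "permutation_importance",
]


class Estimator(Protocol):
    """Minimal fit/predict contract every model in the pipeline satisfies."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Estimator": ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


def _check_pair(y, yhat, min_len: int = 1) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {yhat.shape[0]}")
    if y.shape[0] < min_len:
        raise ValueError(f"need at least {min_len} observations, got {y.shape[0]}")
    return y, yhat


def r2(y, yhat) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot (may be negative)."""
    y, yhat = _check_pair(y, yhat, min_len=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r2 undefined for constant y")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y, yhat = _check_pair(y, yhat, min_len=1)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def ccc(y, yhat) -> float:
    """Lin's concordance correlation coefficient (agreement with y = ŷ)."""
    y, yhat = _check_pair(y, yhat, min_len=2)
    var_y = float(np.var(y))
    var_h = float(np.var(yhat))
    if var_y == 0.0 or var_h == 0.0:
        raise ValueError("ccc undefined when either vector is constant")
    cov = float(np.mean((y - y.mean()) * (yhat - yhat.mean())))
    return 2.0 * cov / (var_y + var_h + float(y.mean() - yhat.mean()) ** 2)


@dataclass(frozen=True)
class FoldRecord:
    fold: int
    train_r2: float
    train_rmse: float
    train_ccc: float
    test_r2: float
    test_rmse: float
    test_ccc: float


@dataclass
class FoldStats:
    """Per-fold and aggregate train/test statistics of one model spec."""

    folds: list[FoldRecord]
    pooled_test_r2: float
    pooled_test_rmse: float
    pooled_test_ccc: float
    oof_predictions: np.ndarray = field(repr=False)

    def _mean(self, attr: str) -> float:
        return float(np.mean([getattr(f, attr) for f in self.folds]))

    @property
    def train_r2(self) -> float:
        return self._mean("train_r2")

    @property
    def train_rmse(self) -> float:
        return self._mean("train_rmse")

    @property
    def train_ccc(self) -> float:
        return self._mean("train_ccc")

    @property
    def test_r2(self) -> float:
        return self._mean("test_r2")

    @property
    def test_rmse(self) -> float:
        return self._mean("test_rmse")

    @property
    def test_ccc(self) -> float:
        return self._mean("test_ccc")

    def to_dict(self) -> dict:
        return {
            "aggregate": {
                "train": {
                    "r2": self.train_r2,
                    "rmse": self.train_rmse,
                    "ccc": self.train_ccc,
                },
                "test": {
                    "r2": self.test_r2,
                    "rmse": self.test_rmse,
                    "ccc": self.test_ccc,
                },
            },
            "pooled_test": {
                "r2": self.pooled_test_r2,
                "rmse": self.pooled_test_rmse,
                "ccc": self.pooled_test_ccc,
            },
            "per_fold": [
                {
                    "fold": f.fold,
                    "train": {"r2": f.train_r2, "rmse": f.train_rmse, "ccc": f.train_ccc},
                    "test": {"r2": f.test_r2, "rmse": f.test_rmse, "ccc": f.test_ccc},
                }
                for f in self.folds
            ],
        }


def cross_validate(
    make_model: Callable[[], Estimator],
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldAssignment,
) -> FoldStats:
    """Fit/score the model spec on every fold of the deterministic split.

    For each fold the model is refit on the other folds, scored on its train
    portion and on the held-out portion.  Aggregates are unweighted means
    over folds; pooled out-of-fold statistics are computed alongside.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    for f in range(folds.n_folds):
        if folds.test_indices(f).size < 2 or folds.train_indices(f).size < 2:
            raise ValueError(f"fold {f} has fewer than 2 observations")

    def _ccc(yv, yh):
        # a constant predictor has zero covariance with any response, so its
        # concordance is the formula's limit 0; keep the standalone ccc strict
        if np.ptp(yh) == 0.0 and np.ptp(yv) > 0.0:
            return 0.0
        return ccc(yv, yh)

    records: list[FoldRecord] = []
    oof = np.full(y.shape, np.nan)
    for f in range(folds.n_folds):
        test_idx = folds.test_indices(f)
        train_idx = folds.train_indices(f)
        model = make_model()
        model.fit(X[train_idx], y[train_idx])
        yhat_train = np.asarray(model.predict(X[train_idx]), dtype=float)
        yhat_test = np.asarray(model.predict(X[test_idx]), dtype=float)
        oof[test_idx] = yhat_test
        records.append(
            FoldRecord(
                fold=f,
                train_r2=r2(y[train_idx], yhat_train),
                train_rmse=rmse(y[train_idx], yhat_train),
                train_ccc=_ccc(y[train_idx], yhat_train),
                test_r2=r2(y[test_idx], yhat_test),
                test_rmse=rmse(y[test_idx], yhat_test),
                test_ccc=_ccc(y[test_idx], yhat_test),
            )
        )
    return FoldStats(
        folds=records,
        pooled_test_r2=r2(y, oof),
        pooled_test_rmse=rmse(y, oof),
        pooled_test_ccc=_ccc(y, oof),
        oof_predictions=oof,
    )


def cv_r2(
    make_model: Callable[[], Estimator],
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldAssignment,
    mode: str = "fold_mean",
) -> float:
    """Aggregate cross-validated test r² — the selection criterion."""
    stats = cross_validate(make_model, X, y, folds)
    if mode == "fold_mean":
        return stats.test_r2
    if mode == "pooled":
        return stats.pooled_test_r2
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ImportanceTable:
    """Permutation importances: mean r² decrease per descriptor."""

    descriptor_names: list[str]
    mean_importance: np.ndarray
    sd_importance: np.ndarray
    n_repeats: int
    seed: int
    baseline_r2: float

    def to_dict(self) -> dict:
        return {
            "baseline_r2": self.baseline_r2,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "importances": {
                name: {"mean": float(m), "sd": float(s)}
                for name, m, s in zip(
                    self.descriptor_names, self.mean_importance, self.sd_importance
                )
            },
        }


def permutation_importance(
    model: Estimator,
    X: np.ndarray,
    y: np.ndarray,
    descriptor_names: list[str],
    n_repeats: int = 30,
    seed: int = 0,
) -> ImportanceTable:
    """Mean decrease in r² when one descriptor column is shuffled.

    The model is *not* refit: the fitted predictor is scored on copies of X
    with a single column permuted.  Importances above 1 are possible when a
    permuted column drives r² negative — expected for a dominant descriptor.

    Each column's permutation stream is seeded from (seed, descriptor name),
    so a descriptor's importance does not depend on where the other columns
    sit or what they are called.
    """
    import zlib

    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[1] != len(descriptor_names):
        raise ValueError("descriptor_names length must match X columns")
    baseline = r2(y, np.asarray(model.predict(X), dtype=float))
    means = np.empty(X.shape[1])
    sds = np.empty(X.shape[1])
    for j, name in enumerate(descriptor_names):
        rng = np.random.default_rng([seed, zlib.crc32(name.encode())])
        drops = np.empty(n_repeats)
        for rep in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            drops[rep] = baseline - r2(y, np.asarray(model.predict(Xp), dtype=float))
        means[j] = drops.mean()
        sds[j] = drops.std(ddof=1) if n_repeats > 1 else 0.0
    return ImportanceTable(
        descriptor_names=list(descriptor_names),
        mean_importance=means,
        sd_importance=sds,
        n_repeats=n_repeats,
        seed=seed,
        baseline_r2=baseline,
    )
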