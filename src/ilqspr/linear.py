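"""Sparse multiple linear regression via OMP with an expulsion search.

The selection strategy targets small interpretable models on a standardized
descriptor matrix:

1.  *OMP* (orthogonal matching pursuit): greedily add the descriptor most
    correlated with the current residual, refit ordinary least squares on
    the active set, repeat to the requested size.  The refit-every-step
    ("orthogonal") variant is used, not plain matching pursuit.
2.  *Expulsion search*: OMP's first pick is always the descriptor most
    correlated with the response, which can shadow better multi-descriptor
    combinations.  The search therefore repeatedly removes the descriptor
    most correlated with y from the candidate pool and reruns OMP, until the
    largest remaining |correlation| drops below a threshold (default 0.4).
    The candidate with the best cross-validated r² wins.
3.  *Model size*: grow k while an extra descriptor corrects at least 20 % of
    the remaining prediction error (1 − r²).

All correlations are Pearson.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .evaluation import cv_r2, r2
from .preprocess import FoldAssignment

__all__ = [
    "LinearModel",
    "OlsEstimator",
    "SelectionRound",
    "SelectionTrace",
    "fit_ols",
    "omp_select",
    "expulsion_search",
    "choose_model_size",
]


@dataclass
class LinearModel:
    """ŷ = β₀ + Σ β_j·X_j over named (standardized) descriptors."""

    descriptor_names: list[str]
    beta0: float
    betas: np.ndarray
    n_train: int

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float).ravel()
        if self.betas.shape[0] != len(self.descriptor_names):
            raise ValueError("one coefficient per descriptor required")
        if not np.all(np.isfinite(self.betas)) or not np.isfinite(self.beta0):
            raise ValueError("non-finite coefficients")

    @property
    def k(self) -> int:
        return len(self.descriptor_names)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.k:
            raise ValueError(f"expected {self.k} columns, got {X.shape[1]}")
        return self.beta0 + X @ self.betas

    def to_json(self, **extra) -> str:
        doc = {
            "model_type": "linear",
            "descriptor_names": self.descriptor_names,
            "beta0": self.beta0,
            "betas": self.betas.tolist(),
            "n_train": self.n_train,
        }
        doc.update(extra)
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        doc = json.loads(text)
        return cls(
            descriptor_names=list(doc["descriptor_names"]),
            beta0=float(doc["beta0"]),
            betas=np.asarray(doc["betas"], dtype=float),
            n_train=int(doc["n_train"]),
        )


class OlsEstimator:
    """fit/predict wrapper over :func:`fit_ols` for the CV harness."""

    def __init__(self) -> None:
        self.model: LinearModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OlsEstimator":
        names = [f"x{j}" for j in range(np.atleast_2d(X).shape[1])]
        self.model = fit_ols(X, y, descriptor_names=names)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("fit before predict")
        return self.model.predict(X)


def _design(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.hstack([np.ones((X.shape[0], 1)), X])


def _dependent_columns(D: np.ndarray, names: list[str]) -> list[str]:
    # QR with pivoting: columns whose R diagonal collapses are dependent.
    from scipy.linalg import qr

    _, R, piv = qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(D.shape) * np.finfo(float).eps
    bad = [piv[i] for i in range(len(diag)) if diag[i] <= tol]
    labels = ["<intercept>"] + names
    return [labels[j] for j in sorted(bad)]


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    descriptor_names: list[str] | None = None,
) -> LinearModel:
    """Ordinary least squares β̂ = (XᵀX)⁻¹Xᵀy with an intercept column.

    Requires n > k + 1 and a full-rank design; a rank-deficient design fails
    with the names of the dependent columns.  On a standardized X the
    intercept equals mean(y).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if descriptor_names is None:
        descriptor_names = [f"x{j}" for j in range(k)]
    if len(descriptor_names) != k:
        raise ValueError("descriptor_names length must match X columns")
    if n <= k + 1:
        raise ValueError(f"need n > k+1 (n={n}, k={k})")
    D = _design(X)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient design; dependent columns: "
            + ", ".join(_dependent_columns(D, list(descriptor_names)))
        )
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    return LinearModel(
        descriptor_names=list(descriptor_names),
        beta0=float(coef[0]),
        betas=coef[1:],
        n_train=n,
    )


def _pearson_to_vector(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    """|corr| is taken on these later; constant columns get correlation 0."""
    Xc = X - X.mean(axis=0)
    vc = v - v.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc.T @ vc) / denom
    return np.where(np.isfinite(corr), corr, 0.0)


def omp_select(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    descriptor_names: list[str] | None = None,
) -> LinearModel:
    """Greedy OMP: add the descriptor most |correlated| with the residual.

    Starts from the intercept-only residual y − mean(y); after each addition
    the active set is refit by OLS and the residual recomputed.  Stops early
    (with a smaller model) if the residual becomes numerically zero.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if descriptor_names is None:
        descriptor_names = [f"x{j}" for j in range(p)]
    if k > p:
        raise ValueError(f"k={k} exceeds available descriptors p={p}")
    active: list[int] = []
    residual = y - y.mean()
    model = LinearModel([], float(y.mean()), np.empty(0), n)
    for _ in range(k):
        if float(residual @ residual) <= 1e-12 * max(1.0, float(y @ y)):
            break  # perfect fit before k descriptors
        corr = np.abs(_pearson_to_vector(X, residual))
        corr[active] = -np.inf
        j = int(np.argmax(corr))
        active.append(j)
        model = fit_ols(
            X[:, active], y, descriptor_names=[descriptor_names[j] for j in active]
        )
        residual = y - model.predict(X[:, active])
    return model


@dataclass(frozen=True)
class SelectionRound:
    """One expulsion round: what was expelled and what OMP then proposed."""

    expelled: str | None
    model: LinearModel
    cv_r2: float


@dataclass
class SelectionTrace:
    rounds: list[SelectionRound] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def best_round(self) -> int:
        scores = [r.cv_r2 for r in self.rounds]
        return int(np.argmax(scores))  # argmax: earliest round wins ties


def expulsion_search(
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldAssignment,
    k: int,
    corr_threshold: float = 0.4,
    descriptor_names: list[str] | None = None,
    score: str = "cv",
) -> tuple[LinearModel, SelectionTrace]:
    """OMP over successively response-decorrelated pools; best cv r² wins.

    Each round runs OMP (size k) on the current pool and records the
    candidate with its cross-validated r².  If the pool still contains a
    descriptor with |corr(X_j, y)| at or above ``corr_threshold``, that
    descriptor is expelled from the pool and the next round starts; once the
    maximum correlation falls below the threshold the search stops with no
    further OMP run.  Expelled descriptors leave only the *selection pool* —
    each candidate is always evaluated on its own descriptors.

    ``score="train"`` ranks candidates by training r² instead of cv r².
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    if descriptor_names is None:
        descriptor_names = [f"x{j}" for j in range(p)]
    if score not in ("cv", "train"):
        raise ValueError(f"score must be 'cv' or 'train', got {score!r}")

    name_index = {d: j for j, d in enumerate(descriptor_names)}

    def _score(model: LinearModel) -> float:
        cols = [name_index[d] for d in model.descriptor_names]
        if score == "train":
            return r2(y, model.predict(X[:, cols]))
        names = list(model.descriptor_names)

        def make():
            est = _FixedSetOls(names)
            return est

        return cv_r2(make, X[:, cols], y, folds)

    pool = list(range(p))
    trace = SelectionTrace()
    abs_corr_y = np.abs(_pearson_to_vector(X, y))
    expelled: str | None = None
    while True:
        candidate = omp_select(
            X[:, pool], y, min(k, len(pool)),
            descriptor_names=[descriptor_names[j] for j in pool],
        )
        trace.rounds.append(SelectionRound(expelled, candidate, _score(candidate)))
        pool_corr = abs_corr_y[pool]
        top = int(np.argmax(pool_corr))
        if pool_corr[top] < corr_threshold:
            trace.stop_reason = (
                f"max |corr(X_j, y)| = {pool_corr[top]:.3f} < {corr_threshold}"
            )
            break
        expelled = descriptor_names[pool[top]]
        del pool[top]
        if len(pool) == 0:
            trace.stop_reason = "pool exhausted"
            break
    best = trace.rounds[trace.best_round]
    return best.model, trace


class _FixedSetOls:
    """OLS estimator over an already-chosen descriptor subset (CV helper)."""

    def __init__(self, names: list[str]) -> None:
        self.names = names
        self.model: LinearModel | None = None

    def fit(self, X, y):
        self.model = fit_ols(X, y, descriptor_names=self.names)
        return self

    def predict(self, X):
        assert self.model is not None
        return self.model.predict(X)


def choose_model_size(
    candidate_builder: Callable[[int], tuple[object, float]],
    k_max: int,
    improvement_fraction: float = 0.20,
) -> tuple[object, int]:
    """Grow k while each extra descriptor corrects ≥ 20 % of the error.

    ``candidate_builder(k)`` returns (model, err) with err = 1 − r²_cv.
    Starting from k = 1, size k+1 is accepted iff
    (err_k − err_{k+1}) / err_k ≥ ``improvement_fraction``; the first
    rejection (or k_max) stops the growth and the last accepted model is
    returned along with its size.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    model, err = candidate_builder(1)
    k = 1
    while k < k_max:
        if err == 0.0:
            break  # nothing left to correct
        nxt_model, nxt_err = candidate_builder(k + 1)
        if (err - nxt_err) / err >= improvement_fraction:
            model, err, k = nxt_model, nxt_err, k + 1
        else:
            break
    return model, k
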