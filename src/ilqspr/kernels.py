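"""Kernel regressions: ε-SVR with an RBF kernel and GPR with a composite kernel.

Both models share the greedy-substitution descriptor selection: grow the
descriptor set one forward step at a time, and after every addition try
substituting each selected descriptor with every pool descriptor, adopting
the single best strictly-improving swap until no swap helps.

SVR prediction is ŷ(x) = Σ_{i∈SV} α_i·K(x_i, x) + b with
K(x, x′) = exp(−γ‖x − x′‖²); the quadratic program behind the duals is
delegated to scikit-learn's SMO solver — the contract here fixes the loss,
the kernel and the γ-token semantics ("auto" → 1/p, "scale" → 1/(p·Var(X))).

GPR uses the kernel sum

    k(x, x′) = σ₀² + x·x′ + exp(−‖x − x′‖²/(2ℓ²)) + noise·δ(x, x′)

(dot-product + squared-exponential + white noise); the predictive mean and
covariance are the standard GP conditionals
f̄* = K(X*,X)·K(X,X)⁻¹·y and V[f*] = K(X*,X*) − K(X*,X)·K(X,X)⁻¹·K(X,X*).
Hyperparameters maximize the log marginal likelihood via seeded multi-start
gradient ascent (scikit-learn's optimizer).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, DotProduct, WhiteKernel
from sklearn.svm import SVR

__all__ = [
    "SvrModel",
    "GprModel",
    "HyperparamGrid",
    "DEFAULT_SVR_GRID",
    "SvrEstimator",
    "GprEstimator",
    "fit_svr",
    "tune_svr",
    "fit_gpr",
    "predict_gpr",
    "greedy_substitution_select",
]

GammaValue = float | str


def resolve_gamma(gamma: GammaValue, X: np.ndarray) -> float:
    """Numeric γ for the RBF kernel; tokens follow the common convention."""
    if isinstance(gamma, str):
        p = X.shape[1]
        if gamma == "auto":
            return 1.0 / p
        if gamma == "scale":
            var = float(X.var())  # variance over all matrix entries
            if var == 0.0:
                raise ValueError("gamma='scale' undefined for constant X")
            return 1.0 / (p * var)
        raise ValueError(f"unknown gamma token {gamma!r}")
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return float(gamma)


@dataclass
class SvrModel:
    """Fitted ε-SVR: support vectors, signed duals α, intercept and kernel γ."""

    descriptor_names: list[str]
    support_indices: np.ndarray
    support_vectors: np.ndarray
    alphas: np.ndarray
    intercept: float
    C: float
    epsilon: float
    gamma: GammaValue
    gamma_value: float

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float).ravel()
        if self.alphas.shape[0] != self.support_indices.shape[0]:
            raise ValueError("one dual coefficient per support vector required")
        if np.any(np.abs(self.alphas) > self.C * (1 + 1e-8)):
            raise ValueError("dual coefficients violate |alpha| <= C")

    @property
    def n_support(self) -> int:
        return int(self.support_indices.shape[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = (
            (X**2).sum(axis=1)[:, None]
            + (self.support_vectors**2).sum(axis=1)[None, :]
            - 2.0 * X @ self.support_vectors.T
        )
        K = np.exp(-self.gamma_value * np.maximum(d2, 0.0))
        return K @ self.alphas + self.intercept

    def to_json(self, **extra) -> str:
        doc = {
            "model_type": "svr",
            "descriptor_names": self.descriptor_names,
            "support_indices": self.support_indices.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "alphas": self.alphas.tolist(),
            "intercept": self.intercept,
            "C": self.C,
            "epsilon": self.epsilon,
            "gamma": self.gamma,
            "gamma_value": self.gamma_value,
        }
        doc.update(extra)
        return json.dumps(doc, indent=2, sort_keys=True)


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.001,
    gamma: GammaValue = "auto",
    descriptor_names: list[str] | None = None,
) -> SvrModel:
    """ε-insensitive SVR with the squared-exponential kernel."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if C <= 0 or epsilon <= 0:
        raise ValueError(f"C and epsilon must be positive (C={C}, epsilon={epsilon})")
    gamma_value = resolve_gamma(gamma, X)
    svr = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma_value, tol=1e-6)
    svr.fit(X, y)
    return SvrModel(
        descriptor_names=(
            descriptor_names if descriptor_names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        ),
        support_indices=svr.support_.astype(int),
        support_vectors=svr.support_vectors_.copy(),
        alphas=svr.dual_coef_.ravel().copy(),
        intercept=float(svr.intercept_[0]),
        C=float(C),
        epsilon=float(epsilon),
        gamma=gamma,
        gamma_value=gamma_value,
    )


class SvrEstimator:
    """fit/predict wrapper with fixed hyperparameters (CV harness)."""

    def __init__(self, C: float = 1.0, epsilon: float = 0.001, gamma: GammaValue = "auto"):
        self.C, self.epsilon, self.gamma = C, epsilon, gamma
        self.model: SvrModel | None = None

    def fit(self, X, y):
        self.model = fit_svr(X, y, C=self.C, epsilon=self.epsilon, gamma=self.gamma)
        return self

    def predict(self, X):
        assert self.model is not None
        return self.model.predict(X)


@dataclass(frozen=True)
class HyperparamGrid:
    """Exhaustive SVR tuning grid; γ entries may be tokens."""

    C_values: tuple[float, ...]
    epsilon_values: tuple[float, ...]
    gamma_values: tuple[GammaValue, ...]

    def __post_init__(self) -> None:
        for label, vals in (("C", self.C_values), ("epsilon", self.epsilon_values)):
            if not vals:
                raise ValueError(f"empty {label} grid")
            if any(v <= 0 for v in vals):
                raise ValueError(f"non-positive value in {label} grid")
        if not self.gamma_values:
            raise ValueError("empty gamma grid")
        for g in self.gamma_values:
            if isinstance(g, str):
                if g not in ("auto", "scale"):
                    raise ValueError(f"unknown gamma token {g!r}")
            elif g <= 0:
                raise ValueError(f"non-positive gamma {g}")

    def __iter__(self):
        return itertools.product(self.C_values, self.epsilon_values, self.gamma_values)


DEFAULT_SVR_GRID = HyperparamGrid(
    C_values=(0.001, 0.005, 0.1, 0.5, 1, 5, 10, 50, 100, 500, 1000),
    epsilon_values=(0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0),
    gamma_values=(0.001, 0.005, 0.01, 0.05, 0.1, "auto", "scale"),
)


def tune_svr(
    X: np.ndarray,
    y: np.ndarray,
    folds,
    grid: HyperparamGrid = DEFAULT_SVR_GRID,
) -> tuple[float, float, GammaValue]:
    """Exhaustive grid search by cross-validated r²; first-in-grid wins ties."""
    from .evaluation import cv_r2

    best: tuple[float, float, GammaValue] | None = None
    best_score = -np.inf
    for C, epsilon, gamma in grid:
        score = cv_r2(
            lambda: SvrEstimator(C=C, epsilon=epsilon, gamma=gamma), X, y, folds
        )
        if score > best_score:  # strict: earlier grid entries win ties
            best, best_score = (C, epsilon, gamma), score
    assert best is not None
    return best


@dataclass
class GprModel:
    """Fitted GP: training data plus the three kernel hyperparameters."""

    descriptor_names: list[str]
    X_train: np.ndarray = field(repr=False)
    y_train: np.ndarray = field(repr=False)
    sigma_0: float
    noise_level: float
    length_scale: float
    log_marginal_likelihood: float
    _gp: GaussianProcessRegressor = field(repr=False)

    @property
    def kernel_params(self) -> dict[str, float]:
        return {
            "sigma_0": self.sigma_0,
            "noise_level": self.noise_level,
            "length_scale": self.length_scale,
        }

    def predict(self, X: np.ndarray) -> np.ndarray:
        mean, _ = predict_gpr(self, X)
        return mean

    def to_json(self, row_ids: list[str] | None = None, **extra) -> str:
        doc = {
            "model_type": "gpr",
            "descriptor_names": self.descriptor_names,
            "kernel_params": self.kernel_params,
            "log_marginal_likelihood": self.log_marginal_likelihood,
            "X_train": self.X_train.tolist(),
            "y_train": self.y_train.tolist(),
        }
        if row_ids is not None:
            doc["row_ids"] = list(row_ids)
        doc.update(extra)
        return json.dumps(doc, indent=2, sort_keys=True)


def _composite_kernel(sigma_0: float, noise_level: float, length_scale: float):
    return (
        DotProduct(sigma_0=sigma_0, sigma_0_bounds=(1e-5, 1e5))
        + RBF(length_scale=length_scale, length_scale_bounds=(1e-3, 1e5))
        + WhiteKernel(noise_level=noise_level, noise_level_bounds=(1e-12, 1e2))
    )


def fit_gpr(
    X: np.ndarray,
    y: np.ndarray,
    sigma_0: float = 1.0,
    noise_level: float = 1e-2,
    length_scale: float = 1.0,
    optimize: bool = True,
    n_restarts: int = 5,
    seed: int = 0,
    descriptor_names: list[str] | None = None,
) -> GprModel:
    """GP regression under the dot-product + RBF + white-noise kernel sum.

    With ``optimize`` the kernel hyperparameters maximize the log marginal
    likelihood from the given initialization plus ``n_restarts`` seeded
    log-uniform restarts.  Cholesky jitter escalates 1e-10 → 1e-6 before the
    fit is declared ill-conditioned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    kernel = _composite_kernel(sigma_0, noise_level, length_scale)
    last_error: Exception | None = None
    for jitter in (1e-10, 1e-8, 1e-6):
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=jitter,
            optimizer="fmin_l_bfgs_b" if optimize else None,
            n_restarts_optimizer=n_restarts if optimize else 0,
            normalize_y=False,
            random_state=seed,
        )
        try:
            with warnings.catch_warnings():
                # multi-start L-BFGS legitimately parks parameters at their
                # bounds on some restarts; that is not an error here
                from sklearn.exceptions import ConvergenceWarning

                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(X, y)
            last_error = None
            break
        except np.linalg.LinAlgError as exc:
            last_error = exc
    if last_error is not None:
        raise np.linalg.LinAlgError(
            f"GPR Cholesky failed even with jitter 1e-6: {last_error}"
        )
    k1, k2, k3 = gp.kernel_.k1.k1, gp.kernel_.k1.k2, gp.kernel_.k2
    return GprModel(
        descriptor_names=(
            descriptor_names if descriptor_names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        ),
        X_train=X.copy(),
        y_train=y.copy(),
        sigma_0=float(k1.sigma_0),
        noise_level=float(k3.noise_level),
        length_scale=float(k2.length_scale),
        log_marginal_likelihood=float(gp.log_marginal_likelihood_value_),
        _gp=gp,
    )


def predict_gpr(model: GprModel, X_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean f̄* and covariance V[f*] at the query points."""
    X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
    expected = len(model.descriptor_names)
    if X_star.shape[1] != expected:
        raise ValueError(
            f"query matrix has {X_star.shape[1]} columns; model needs "
            f"{expected} ({model.descriptor_names})"
        )
    mean, cov = model._gp.predict(X_star, return_cov=True)
    cov = 0.5 * (cov + cov.T)  # symmetrize away round-off
    return mean, cov


class GprEstimator:
    """fit/predict wrapper for the CV harness; optimization configurable."""

    def __init__(
        self,
        sigma_0: float = 1.0,
        noise_level: float = 1e-2,
        length_scale: float = 1.0,
        optimize: bool = True,
        n_restarts: int = 0,
        seed: int = 0,
    ):
        self.params = dict(
            sigma_0=sigma_0, noise_level=noise_level, length_scale=length_scale
        )
        self.optimize = optimize
        self.n_restarts = n_restarts
        self.seed = seed
        self.model: GprModel | None = None

    def fit(self, X, y):
        self.model = fit_gpr(
            X, y, optimize=self.optimize, n_restarts=self.n_restarts,
            seed=self.seed, **self.params,
        )
        return self

    def predict(self, X):
        assert self.model is not None
        return self.model.predict(X)


def greedy_substitution_select(
    score_fn: Callable[[tuple[str, ...]], float],
    pool: Sequence[str],
    k: int,
) -> tuple[list[str], float]:
    """Forward selection with exhaustive single-descriptor substitution.

    ``score_fn`` maps a descriptor-name tuple to its cross-validated r² and
    must be deterministic.  After each forward addition, every selected
    position is tried against every unused pool descriptor; the single swap
    with the largest strict improvement is adopted, and passes repeat until
    no swap improves.  Scores are memoized on the descriptor set, so the
    same subset is never evaluated twice.
    """
    pool = list(pool)
    if len(pool) < k:
        raise ValueError(f"pool of {len(pool)} descriptors cannot yield k={k}")
    if len(set(pool)) != len(pool):
        raise ValueError("duplicate names in pool")

    cache: dict[frozenset, float] = {}

    def score(names: list[str]) -> float:
        key = frozenset(names)
        if key not in cache:
            cache[key] = float(score_fn(tuple(names)))
        return cache[key]

    selected: list[str] = []
    current = -np.inf
    for _ in range(k):
        # forward step: best single addition
        remaining = [d for d in pool if d not in selected]
        scores = [score(selected + [d]) for d in remaining]
        best = int(np.argmax(scores))
        selected = selected + [remaining[best]]
        current = scores[best]
        # substitution passes: adopt the single best strictly-improving swap
        improved = True
        while improved:
            improved = False
            best_swap: tuple[int, str, float] | None = None
            for pos in range(len(selected)):
                for d in pool:
                    if d in selected:
                        continue
                    trial = selected[:pos] + [d] + selected[pos + 1 :]
                    s = score(trial)
                    if s > current and (best_swap is None or s > best_swap[2]):
                        best_swap = (pos, d, s)
            if best_swap is not None:
                pos, d, s = best_swap
                selected = selected[:pos] + [d] + selected[pos + 1 :]
                current = s
                improved = True
    return selected, current
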