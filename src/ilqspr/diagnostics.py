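"""Influence and applicability-domain diagnostics for linear models.

For a fitted model with design matrix X (constant column appended):

* leverage h_ii — diagonal of the hat matrix H = X(XᵀX)⁻¹Xᵀ; the critical
  ("high") threshold is h*₃ = 3(k+1)/n, with 2(k+1)/n as the conventional
  moderate companion;
* internally standardized residual r_i = (ŷ_i − y_i)/(σ̂·√(1 − h_ii)) with
  σ̂² = eᵀe/(n − k − 1) and e_i = y_i − ŷ_i.  Note the sign convention:
  positive r_i means the model over-predicts observation i.  |r_i| > 2 marks
  a moderate residual, |r_i| > 3 a likely outlier;
* Cook's distance D_i = r_i²/(k+1) · h_ii/(1 − h_ii); D_i > 1 flags an
  observation whose removal would move the fit appreciably.

Observations passing these thresholds delimit the applicability domain of a
structure–property model: predictions for cations structurally similar to
high-leverage/high-residual training points deserve extra scrutiny.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linear import LinearModel

__all__ = [
    "InfluenceTable",
    "leverage",
    "standardized_residuals",
    "cooks_distance",
    "influence_table",
    "influence_report",
]


def _design(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.hstack([np.ones((X.shape[0], 1)), X])


def leverage(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Hat-matrix diagonal and the critical leverage 3(k+1)/n."""
    D = _design(X)
    n, cols = D.shape
    if np.linalg.matrix_rank(D) < cols:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    # h_ii = row-wise quadratic form, via least-squares solve for stability
    G = np.linalg.solve(D.T @ D, D.T)
    h = np.einsum("ij,ji->i", D, G)
    k = cols - 1
    return h, 3.0 * (k + 1) / n


def standardized_residuals(
    model: LinearModel, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Internally studentized residuals, over-prediction positive.

    Entries with h_ii numerically 1 are returned as NaN (the residual is
    pinned to zero there and the ratio is undefined) rather than ±inf.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k+1 (n={n}, k={k})")
    h, _ = leverage(X)
    e = y - model.predict(X)
    sigma2 = float(e @ e) / (n - k - 1)
    scale2 = max(1.0, float(y @ y) / n)
    if sigma2 <= 1e-24 * scale2:  # numerically perfect fit
        return np.zeros(n)
    denom = np.sqrt(sigma2) * np.sqrt(np.clip(1.0 - h, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (-e) / denom  # ŷ − y: over-prediction positive
    r[~np.isfinite(r)] = np.nan
    return r


def cooks_distance(h: np.ndarray, r: np.ndarray, k: int) -> np.ndarray:
    """D_i = r_i²/(k+1) · h_ii/(1−h_ii); NaN residuals propagate."""
    h = np.asarray(h, dtype=float)
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (r**2) / (k + 1) * h / (1.0 - h)
    return d


@dataclass
class InfluenceTable:
    """Per-observation influence diagnostics with threshold flags."""

    ids: list[str]
    leverage: np.ndarray
    residual: np.ndarray
    std_residual: np.ndarray
    cooks_d: np.ndarray
    sigma2: float
    h_critical: float
    h_moderate: float
    k: int
    n: int

    @property
    def moderate_leverage(self) -> np.ndarray:
        return (self.leverage > self.h_moderate) & (self.leverage <= self.h_critical)

    @property
    def high_leverage(self) -> np.ndarray:
        return self.leverage > self.h_critical

    @property
    def moderate_residual(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.abs(self.std_residual) > 2.0

    @property
    def high_residual(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.abs(self.std_residual) > 3.0

    @property
    def influential(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.cooks_d > 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "leverage": self.leverage,
                "residual": self.residual,
                "std_residual": self.std_residual,
                "cooks_d": self.cooks_d,
                "moderate_leverage": self.moderate_leverage,
                "high_leverage": self.high_leverage,
                "moderate_residual": self.moderate_residual,
                "high_residual": self.high_residual,
                "influential": self.influential,
            }
        )


def influence_table(
    model: LinearModel,
    X: np.ndarray,
    y: np.ndarray,
    ids: list[str] | None = None,
    moderate_factor: float = 2.0,
) -> InfluenceTable:
    """Assemble leverage, residual and Cook's-distance diagnostics.

    ``moderate_factor`` sets the moderate-leverage threshold at
    factor·(k+1)/n (default 2, the conventional companion to the high
    threshold 3(k+1)/n).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    h, h_crit = leverage(X)
    r = standardized_residuals(model, X, y)
    e = y - model.predict(X)
    sigma2 = float(e @ e) / (n - k - 1)
    d = cooks_distance(h, r, k)
    return InfluenceTable(
        ids=ids if ids is not None else [str(i) for i in range(n)],
        leverage=h,
        residual=e,
        std_residual=r,
        cooks_d=d,
        sigma2=sigma2,
        h_critical=h_crit,
        h_moderate=moderate_factor * (k + 1) / n,
        k=k,
        n=n,
    )


def influence_report(table: InfluenceTable) -> dict:
    """Flag-grouped observation lists plus influence-plot scatter data.

    The scatter data (leverage vs standardized residual, point size
    proportional to D_i) reproduces the construction of the standard
    influence plot.
    """

    def _ids(mask: np.ndarray) -> list[str]:
        return [table.ids[i] for i in np.flatnonzero(mask)]

    frame = table.to_frame()
    return {
        "n": table.n,
        "k": table.k,
        "sigma2": table.sigma2,
        "h_critical": table.h_critical,
        "h_moderate": table.h_moderate,
        "flagged": {
            "moderate_leverage": _ids(table.moderate_leverage),
            "high_leverage": _ids(table.high_leverage),
            "moderate_residual": _ids(table.moderate_residual),
            "high_residual": _ids(table.high_residual),
            "influential": _ids(table.influential),
        },
        "undefined_residuals": _ids(np.isnan(table.std_residual)),
        "scatter": frame[["id", "leverage", "std_residual", "cooks_d"]],
    }
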