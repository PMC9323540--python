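"""Descriptor pruning, standardization and the deterministic 10-fold split.

The preparation workflow is: drop unusable descriptor columns (missing
values, zero variance, collinear duplicates), standardize the survivors to
mean 0 / sd 1 over the full series, then partition the cations into folds by
ranking them on logK and dealing every tenth cation into the same fold.
Standardization uses full-series statistics computed once before fold
splitting; the mild information leakage this implies is a documented property
of the workflow, not an accident.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DescriptorMatrix, PropertySeries

__all__ = [
    "RemovedColumn",
    "FoldAssignment",
    "prune_descriptors",
    "standardize",
    "apply_standardization",
    "assign_folds",
]


@dataclass(frozen=True)
class RemovedColumn:
    """Why a descriptor column was dropped during pruning."""

    name: str
    reason: str  # "missing" | "constant" | "collinear"
    detail: str = ""


@dataclass(frozen=True)
class FoldAssignment:
    """Every-tenth-cation partition over the logK-sorted series.

    ``fold_of[i]`` is the fold index of observation ``i`` (original row
    order).  The observation ranked ``j`` in ascending-logK order sits in
    fold ``j mod n_folds``, which stratifies each fold across the whole
    response range.
    """

    n_folds: int
    fold_of: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "fold_of", np.asarray(self.fold_of, dtype=int))

    @property
    def n(self) -> int:
        return self.fold_of.shape[0]

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)

    def fold_sizes(self) -> list[int]:
        return [int(np.sum(self.fold_of == f)) for f in range(self.n_folds)]


def prune_descriptors(
    matrix: DescriptorMatrix,
    collinearity_threshold: float = 0.95,
) -> tuple[DescriptorMatrix, list[RemovedColumn]]:
    """Remove missing-value, constant and collinear descriptor columns.

    Pass order: (1) any column containing a non-finite value goes
    ("missing"); (2) zero-variance columns go ("constant"); (3) scanning the
    survivors in input order, a column whose absolute Pearson correlation
    with an already-retained column reaches ``collinearity_threshold`` goes
    ("collinear", recording its partner).  First-in-order wins every tie, so
    the result is reproducible without randomness.
    """
    if matrix.standardized:
        raise ValueError("prune before standardizing, not after")
    if not 0.0 < collinearity_threshold <= 1.0:
        raise ValueError(
            f"collinearity_threshold must be in (0, 1], got {collinearity_threshold}"
        )
    removed: list[RemovedColumn] = []
    values = matrix.values
    keep: list[int] = []
    for j, name in enumerate(matrix.descriptor_names):
        col = values[:, j]
        if not np.all(np.isfinite(col)):
            removed.append(RemovedColumn(name, "missing"))
        elif np.ptp(col) == 0.0:
            removed.append(RemovedColumn(name, "constant"))
        else:
            keep.append(j)

    # Collinearity scan on the survivors; correlations against retained
    # columns only, computed on centered/normalized copies for speed.
    centered = values[:, keep] - values[:, keep].mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    unit = centered / norms
    retained: list[int] = []  # positions within `keep`
    for pos in range(len(keep)):
        name = matrix.descriptor_names[keep[pos]]
        if retained:
            corr = np.abs(unit[:, retained].T @ unit[:, pos])
            hit = np.flatnonzero(corr >= collinearity_threshold)
            if hit.size:
                partner = matrix.descriptor_names[keep[retained[hit[0]]]]
                removed.append(
                    RemovedColumn(
                        name,
                        "collinear",
                        f"|r|={corr[hit[0]]:.4f} with {partner}",
                    )
                )
                continue
        retained.append(pos)

    kept_idx = [keep[pos] for pos in retained]
    if len(kept_idx) < 2:
        raise ValueError(
            f"pruning left {len(kept_idx)} descriptor(s); need at least 2"
        )
    pruned = DescriptorMatrix(
        row_ids=list(matrix.row_ids),
        descriptor_names=[matrix.descriptor_names[j] for j in kept_idx],
        values=values[:, kept_idx].copy(),
    )
    return pruned, removed


def standardize(matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Scale every column to mean 0, sample sd 1; store the affine map.

    Sample standard deviation (ddof=1) is used so a standardized column has
    sd exactly 1 under the same convention downstream statistics use.
    """
    values = matrix.values
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0.0)
    if zero.size:
        names = [matrix.descriptor_names[j] for j in zero]
        raise ValueError(
            f"zero standard deviation in columns {names}; prune before standardizing"
        )
    return DescriptorMatrix(
        row_ids=list(matrix.row_ids),
        descriptor_names=list(matrix.descriptor_names),
        values=(values - means) / sds,
        standardized=True,
        column_means=means,
        column_sds=sds,
    )


def apply_standardization(
    matrix: DescriptorMatrix, reference: DescriptorMatrix
) -> DescriptorMatrix:
    """Standardize new cations with a fitted matrix's stored means/sds."""
    if reference.column_means is None or reference.column_sds is None:
        raise ValueError("reference matrix has no stored standardization")
    sub = matrix.subset(list(reference.descriptor_names))
    return DescriptorMatrix(
        row_ids=list(sub.row_ids),
        descriptor_names=list(sub.descriptor_names),
        values=(sub.values - reference.column_means) / reference.column_sds,
        standardized=True,
        column_means=reference.column_means.copy(),
        column_sds=reference.column_sds.copy(),
    )


def assign_folds(series_or_y, n_folds: int = 10) -> FoldAssignment:
    """Deterministic stratified folds: sort by logK, deal round-robin.

    Accepts a :class:`PropertySeries` or a plain response vector.  Ties in
    logK are broken by input order (stable sort), so the assignment is
    seedless and reproducible.
    """
    if isinstance(series_or_y, PropertySeries):
        y = series_or_y.y
    else:
        y = np.asarray(series_or_y, dtype=float)
    n = y.shape[0]
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds n={n}")
    order = np.argsort(y, kind="stable")
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % n_folds
    return FoldAssignment(n_folds=n_folds, fold_of=fold_of)
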