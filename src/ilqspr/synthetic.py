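"""Synthetic descriptor matrices with planted sparse structure.

The generator emulates the statistical shape of a small QSPR campaign:
n ≈ 60 cations, a few hundred numeric descriptors with block correlation,
a sparse true model of ~4 standardized descriptors whose signal-to-noise is
calibrated in closed form to a target population r², plus collinear and
constant decoy columns and optional injected high-leverage/high-residual
observations.  It produces numeric tables directly — no chemistry is
simulated — so every pipeline stage is testable without any download.

Base columns are drawn with population mean 0 and variance 1 (block factor
model: x = √ρ·z_block + √(1−ρ)·ε), so the planted coefficients live on the
standardized scale the models use.  Noise variance is computed analytically
from the planted coefficients and the block covariance, never by trial
fitting, which keeps generation O(n·p) and exactly seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DescriptorMatrix

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "make_planted_linear",
    "make_planted_nonlinear",
    "inject_anomalies",
    "save_synthetic",
]

_BLOCK_SIZE = 5  # columns per correlated block


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the generator; the defaults are the reference conditions."""

    seed: int
    n: int = 60
    p: int = 200
    k_true: int = 4
    beta_true: tuple[float, ...] = (1.0, -0.8, 0.6, -0.4)
    target_r2: float = 0.9
    n_collinear_decoys: int = 5
    n_constant_decoys: int = 5
    n_outliers: int = 0
    correlation_block_rho: float = 0.5
    nonlinear_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if len(self.beta_true) != self.k_true:
            raise ValueError(
                f"beta_true has {len(self.beta_true)} entries, k_true={self.k_true}"
            )
        if self.k_true > self.p:
            raise ValueError("k_true cannot exceed p")
        if not 0.0 < self.target_r2 <= 1.0:
            raise ValueError("target_r2 must be in (0, 1]")  # 1.0 = noiseless
        if not 0.0 <= self.correlation_block_rho < 1.0:
            raise ValueError("correlation_block_rho must be in [0, 1)")
        if self.k_true > -(-self.p // _BLOCK_SIZE):
            raise ValueError("not enough correlation blocks for k_true signals")


@dataclass
class PlantedTruth:
    """What the generator planted: the oracle for recovery tests."""

    signal_indices: list[int]
    signal_names: list[str]
    beta_true: np.ndarray
    noise_sd: float
    seed: int
    interaction: dict | None = None  # {"pair": [i, j], "amplitude": a}
    anomalies: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "signal_indices": list(map(int, self.signal_indices)),
            "signal_names": self.signal_names,
            "beta_true": self.beta_true.tolist(),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "interaction": self.interaction,
            "anomalies": self.anomalies,
        }


def _draw_base(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Block-correlated standard-normal columns, population unit variance."""
    n, p, rho = spec.n, spec.p, spec.correlation_block_rho
    n_blocks = -(-p // _BLOCK_SIZE)
    z = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, p))
    block_of = np.arange(p) // _BLOCK_SIZE
    return np.sqrt(rho) * z[:, block_of] + np.sqrt(1.0 - rho) * eps


def _signal_layout(spec: SyntheticSpec, rng: np.random.Generator) -> list[int]:
    """One signal column per distinct block → independent signal columns."""
    n_blocks = -(-spec.p // _BLOCK_SIZE)
    blocks = rng.choice(n_blocks, size=spec.k_true, replace=False)
    return sorted(int(b) * _BLOCK_SIZE for b in blocks)


def _assemble(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    X_base: np.ndarray,
    signal: list[int],
    y: np.ndarray,
    noise_sd: float,
    interaction: dict | None,
) -> tuple[DescriptorMatrix, np.ndarray, PlantedTruth]:
    names = [f"D{j:04d}" for j in range(spec.p)]
    columns = [X_base]
    # collinear decoys: near-copies of signal columns, |r| ≈ 0.995
    for i in range(spec.n_collinear_decoys):
        src = signal[i % len(signal)]
        decoy = X_base[:, src] + 0.1 * rng.standard_normal(spec.n)
        columns.append(decoy[:, None])
        names.append(f"COLL{i:02d}_of_{names[src]}")
    for i in range(spec.n_constant_decoys):
        columns.append(np.full((spec.n, 1), float(i)))
        names.append(f"CONST{i:02d}")
    values = np.hstack(columns)
    matrix = DescriptorMatrix(
        row_ids=[f"obs{i:03d}" for i in range(spec.n)],
        descriptor_names=names,
        values=values,
    )
    truth = PlantedTruth(
        signal_indices=list(signal),
        signal_names=[names[j] for j in signal],
        beta_true=np.asarray(spec.beta_true, dtype=float),
        noise_sd=noise_sd,
        seed=spec.seed,
        interaction=interaction,
    )
    return matrix, y, truth


def make_planted_linear(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, np.ndarray, PlantedTruth]:
    """y = Σ β_j·X_j + ε with ε calibrated so population r² = target_r2.

    The signal columns sit in distinct correlation blocks and are therefore
    mutually independent, so Var(signal) = Σβ² exactly and the noise sd has
    the closed form  σ = sqrt(Σβ²·(1 − r²)/r²).
    """
    rng = np.random.default_rng(spec.seed)
    X_base = _draw_base(spec, rng)
    signal = _signal_layout(spec, rng)
    beta = np.asarray(spec.beta_true, dtype=float)
    var_signal = float(beta @ beta)
    noise_sd = float(np.sqrt(var_signal * (1.0 - spec.target_r2) / spec.target_r2))
    y = X_base[:, signal] @ beta + noise_sd * rng.standard_normal(spec.n)
    return _assemble(spec, rng, X_base, signal, y, noise_sd, None)


def make_planted_nonlinear(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, np.ndarray, PlantedTruth]:
    """Linear signal plus a smooth interaction a·X_s0·X_s1.

    The interaction term has unit variance and is uncorrelated with the
    linear part (odd moments vanish), so the total signal variance is
    Σβ² + a² and the noise calibration stays closed-form.  Amplitude 0
    reduces exactly to :func:`make_planted_linear`'s output distribution.
    """
    rng = np.random.default_rng(spec.seed)
    X_base = _draw_base(spec, rng)
    signal = _signal_layout(spec, rng)
    beta = np.asarray(spec.beta_true, dtype=float)
    a = float(spec.nonlinear_amplitude)
    var_signal = float(beta @ beta) + a * a
    noise_sd = float(np.sqrt(var_signal * (1.0 - spec.target_r2) / spec.target_r2))
    linear = X_base[:, signal] @ beta
    inter = a * X_base[:, signal[0]] * X_base[:, signal[1]]
    y = linear + inter + noise_sd * rng.standard_normal(spec.n)
    interaction = {"pair": [signal[0], signal[1]], "amplitude": a}
    return _assemble(spec, rng, X_base, signal, y, noise_sd, interaction)


def inject_anomalies(
    matrix: DescriptorMatrix,
    y: np.ndarray,
    truth: PlantedTruth,
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, np.ndarray, PlantedTruth]:
    """Append ``spec.n_outliers`` high-leverage and as many high-residual rows.

    High-leverage rows place the signal descriptors at ±4 (4 population sd)
    with response on the planted surface; high-residual rows are ordinary
    draws whose response is shifted by 5·noise sd.  Appended-row indices are
    recorded on the returned truth.  ``n_outliers = 0`` is the identity.
    """
    if spec.n_outliers == 0:
        return matrix, np.asarray(y, dtype=float), truth
    if spec.n_outliers >= spec.n / 10:
        raise ValueError("n_outliers must stay below n/10")
    rng = np.random.default_rng(spec.seed + 1_000_003)
    beta = truth.beta_true
    p_total = matrix.p
    sig = truth.signal_indices

    new_rows, new_y, lev_idx, res_idx = [], [], [], []
    next_index = matrix.n
    for _ in range(spec.n_outliers):
        row = rng.standard_normal(p_total)
        row[sig] = 4.0 * np.sign(rng.standard_normal(len(sig)))
        yv = float(row[sig] @ beta) + truth.noise_sd * float(rng.standard_normal())
        new_rows.append(row)
        new_y.append(yv)
        lev_idx.append(next_index)
        next_index += 1
    for _ in range(spec.n_outliers):
        row = rng.standard_normal(p_total)
        yv = float(row[sig] @ beta) + 5.0 * truth.noise_sd
        new_rows.append(row)
        new_y.append(yv)
        res_idx.append(next_index)
        next_index += 1

    # keep constant decoy columns constant in the appended rows
    for j, name in enumerate(matrix.descriptor_names):
        if name.startswith("CONST"):
            for row in new_rows:
                row[j] = matrix.values[0, j]

    out = DescriptorMatrix(
        row_ids=list(matrix.row_ids)
        + [f"anom{i:02d}" for i in range(2 * spec.n_outliers)],
        descriptor_names=list(matrix.descriptor_names),
        values=np.vstack([matrix.values, np.vstack(new_rows)]),
    )
    truth_out = PlantedTruth(
        signal_indices=list(truth.signal_indices),
        signal_names=list(truth.signal_names),
        beta_true=truth.beta_true.copy(),
        noise_sd=truth.noise_sd,
        seed=truth.seed,
        interaction=truth.interaction,
        anomalies={"leverage": lev_idx, "residual": res_idx},
    )
    return out, np.concatenate([np.asarray(y, dtype=float), new_y]), truth_out


def save_synthetic(
    outdir,
    matrix: DescriptorMatrix,
    y: np.ndarray,
    truth: PlantedTruth,
) -> dict[str, Path]:
    """Write series.csv, descriptors.csv and truth.json to a directory.

    The series file uses a placeholder SMILES ("C") in every row: the
    synthetic generator plants numeric structure, not chemistry, but the
    files exercise exactly the delimited-text readers real data would use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "series": outdir / "series.csv",
        "descriptors": outdir / "descriptors.csv",
        "truth": outdir / "truth.json",
    }
    pd.DataFrame(
        {"id": matrix.row_ids, "smiles": ["C"] * matrix.n, "logK": np.asarray(y)}
    ).to_csv(paths["series"], index=False)
    matrix.to_csv(paths["descriptors"])
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))
    return paths
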