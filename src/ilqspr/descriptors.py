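"""2D molecular descriptor computation behind a pluggable engine adapter.

The pipeline never commits to one descriptor package: any callable mapping a
SMILES string to an ordered ``{name: value}`` dict can serve as the engine.
The shipped engine wraps RDKit's 2D descriptor list.  Non-finite engine
outputs are stored as NaN and handled later by column pruning, never by
dropping cations (n is small and precious in this domain).
"""

from __future__ import annotations

from typing import Callable, Mapping, Protocol

import numpy as np

from .io import DescriptorMatrix, PropertySeries

__all__ = ["DescriptorEngine", "RDKitDescriptorEngine", "compute_descriptors"]


class DescriptorEngine(Protocol):
    """Adapter contract: SMILES in, ordered name→value mapping out.

    The engine must be deterministic and return the same key order for every
    molecule; it should raise ``ValueError`` for unparseable SMILES.
    """

    def __call__(self, smiles: str) -> Mapping[str, float]: ...


class RDKitDescriptorEngine:
    """All of RDKit's 2D descriptors (no conformers are ever generated).

    ``Descriptors.CalcMolDescriptors`` covers constitutional counts, Chi and
    Kappa indices, E-state and VSA sums, BCUT eigenvalues, autocorrelations,
    Crippen logP/MR — the same descriptor families interpreted in
    gas–ionic-liquid partition models.  Descriptor failures surface as NaN.
    """

    def __init__(self) -> None:
        from rdkit import Chem
        from rdkit.Chem import Descriptors

        self._chem = Chem
        self._descriptors = Descriptors

    def __call__(self, smiles: str) -> Mapping[str, float]:
        mol = self._chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return self._descriptors.CalcMolDescriptors(mol, missingVal=float("nan"))


def compute_descriptors(
    series: PropertySeries,
    engine: Callable[[str], Mapping[str, float]],
) -> DescriptorMatrix:
    """Run the engine over every cation and assemble the descriptor matrix.

    One row per record, in series order; columns are the engine's descriptor
    set in the engine's order.  Raises ``ValueError`` naming the cation whose
    SMILES the engine rejects.
    """
    names: list[str] | None = None
    rows: list[np.ndarray] = []
    for record in series.records:
        try:
            result = engine(record.smiles)
        except ValueError as exc:
            raise ValueError(
                f"descriptor engine failed for cation {record.cation_id!r}: {exc}"
            ) from exc
        if names is None:
            names = list(result.keys())
        elif list(result.keys()) != names:
            raise ValueError(
                f"engine returned inconsistent descriptor set for "
                f"{record.cation_id!r}"
            )
        row = np.array([float(result[d]) for d in names], dtype=float)
        rows.append(row)
    assert names is not None
    return DescriptorMatrix(
        row_ids=series.ids,
        descriptor_names=names,
        values=np.vstack(rows),
    )
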