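"""Property series and descriptor-matrix containers with delimited-text I/O.

A *property series* is one solute's list of ionic-liquid cations, each with a
SMILES string and an experimental gas–ionic-liquid partition coefficient
log10(K) at 298 K.  The anion is constant across a series (and is never
featurized), so the cation identifier alone labels an observation.

A *descriptor matrix* is the cations × molecular-descriptors numeric table
(the design matrix X of every downstream model), together with its
standardization state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CationRecord",
    "PropertySeries",
    "DescriptorMatrix",
    "read_series",
    "write_series",
]


@dataclass(frozen=True)
class CationRecord:
    """One cation: short label, SMILES (charge included) and measured logK."""

    cation_id: str
    smiles: str
    logK: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.logK):
            raise ValueError(f"logK for {self.cation_id!r} is not finite: {self.logK}")


@dataclass(frozen=True)
class PropertySeries:
    """One solute's ordered collection of cation records.

    ``solute`` is typically one of hexane / cyclohexane / benzene but any
    label is accepted.  Cation ids must be unique; at least two records are
    required for anything downstream to be meaningful.
    """

    solute: str
    records: tuple[CationRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError(
                f"property series {self.solute!r} needs >= 2 records, "
                f"got {len(self.records)}"
            )
        ids = [r.cation_id for r in self.records]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise ValueError(f"duplicate cation_id {i!r} in series {self.solute!r}")
            seen.add(i)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.cation_id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def y(self) -> np.ndarray:
        """logK values as a float vector, in record order."""
        return np.array([r.logK for r in self.records], dtype=float)


@dataclass
class DescriptorMatrix:
    """Cations × descriptors table: the X matrix plus bookkeeping.

    ``column_means``/``column_sds`` are populated when the matrix is
    standardized so that the same affine map can be applied to descriptors of
    new cations at prediction time.
    """

    row_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.row_ids):
            raise ValueError(f"{len(self.row_ids)} row ids but {n} rows")
        if p != len(self.descriptor_names):
            raise ValueError(f"{len(self.descriptor_names)} names but {p} columns")
        if len(set(self.descriptor_names)) != p:
            dupes = sorted(
                {d for d in self.descriptor_names if self.descriptor_names.count(d) > 1}
            )
            raise ValueError(f"duplicate descriptor names: {dupes}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.descriptor_names.index(name)]

    def subset(self, names: list[str]) -> "DescriptorMatrix":
        """New matrix restricted to ``names``, in the order given."""
        missing = [d for d in names if d not in self.descriptor_names]
        if missing:
            raise KeyError(f"descriptors not in matrix: {missing}")
        idx = [self.descriptor_names.index(d) for d in names]
        return DescriptorMatrix(
            row_ids=list(self.row_ids),
            descriptor_names=list(names),
            values=self.values[:, idx].copy(),
            standardized=self.standardized,
            column_means=None if self.column_means is None else self.column_means[idx],
            column_sds=None if self.column_sds is None else self.column_sds[idx],
        )

    def copy(self) -> "DescriptorMatrix":
        return replace(
            self,
            row_ids=list(self.row_ids),
            descriptor_names=list(self.descriptor_names),
            values=self.values.copy(),
            column_means=None if self.column_means is None else self.column_means.copy(),
            column_sds=None if self.column_sds is None else self.column_sds.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.row_ids, name="id"),
            columns=self.descriptor_names,
        )

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, standardized: bool = False) -> "DescriptorMatrix":
        return cls(
            row_ids=[str(i) for i in frame.index],
            descriptor_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            standardized=standardized,
        )

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "DescriptorMatrix":
        return cls.from_frame(pd.read_csv(path, sep=sep, index_col=0))


def read_series(
    path,
    solute: str | None = None,
    sep: str = ",",
    id_column: str = "id",
    smiles_column: str = "smiles",
    logk_column: str = "logK",
) -> PropertySeries:
    """Read a property series from delimited text.

    The file needs a header with the id, SMILES and logK columns (names
    configurable).  Row order is preserved.  Errors name the offending row or
    column so bad input files are diagnosable.
    """
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no records in {path}") from None
    if frame.empty:
        raise ValueError(f"no records in {path}")
    for col in (id_column, smiles_column, logk_column):
        if col not in frame.columns:
            raise ValueError(
                f"missing column {col!r} in {path}; found {list(frame.columns)}"
            )
    records = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        raw = getattr(row, logk_column, None)
        if raw is None:  # attribute name mangled (e.g. non-identifier header)
            raw = frame[logk_column].iloc[row_number - 2]
        try:
            value = float(raw)
        except (TypeError, ValueError):
            raise ValueError(
                f"unparseable logK {raw!r} at row {row_number} of {path}"
            ) from None
        if not math.isfinite(value):
            raise ValueError(f"non-finite logK at row {row_number} of {path}")
        records.append(
            CationRecord(
                cation_id=str(frame[id_column].iloc[row_number - 2]),
                smiles=str(frame[smiles_column].iloc[row_number - 2]),
                logK=value,
            )
        )
    return PropertySeries(
        solute=solute if solute is not None else "unknown",
        records=tuple(records),
    )


def write_series(series: PropertySeries, path, sep: str = ",") -> None:
    pd.DataFrame(
        {
            "id": series.ids,
            "smiles": series.smiles,
            "logK": series.y,
        }
    ).to_csv(path, sep=sep, index=False)
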