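"""Core containers: province attribute tables and the network matrices.

The containers are deliberately thin. A :class:`ProvinceTable` wraps an
ordered list of :class:`ProvinceRecord`; the matrices wrap a numpy array
plus the province name order, which every downstream table preserves.
All validation happens at construction so later stages can assume clean
inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSizeError, SchemaError

#: Columns of the canonical province CSV schema, in order. ``population``,
#: ``x`` and ``y`` are optional on input.
PROVINCE_COLUMNS = ("name", "P", "H", "G", "g", "R", "population", "x", "y")


@dataclass(frozen=True)
class ProvinceRecord:
    """Per-province attributes feeding the gravity model.

    Parameters
    ----------
    name : str
        Unique province identifier.
    P : float
        Annual outpatient/medical visits (volume, > 0).
    H : float
        Total health expenditure (currency units, > 0).
    G : float
        Gross domestic product (currency units, > 0).
    g : float
        GDP per capita (currency units, > 0).
    R : int
        Number of tertiary public hospitals (>= 0).
    population : float, optional
        Resident population (> 0 when given).
    x, y : float, optional
        Planar or geographic capital coordinates.
    """

    name: str
    P: float
    H: float
    G: float
    g: float
    R: int
    population: float | None = None
    x: float | None = None
    y: float | None = None

    def __post_init__(self) -> None:
        for attr in ("P", "H", "G", "g"):
            value = getattr(self, attr)
            if not math.isfinite(value) or value <= 0:
                raise SchemaError(
                    f"province {self.name!r}: {attr} must be finite and > 0, got {value!r}"
                )
        if int(self.R) != self.R or self.R < 0:
            raise SchemaError(
                f"province {self.name!r}: R must be a nonnegative integer, got {self.R!r}"
            )
        if self.population is not None and self.population <= 0:
            raise SchemaError(
                f"province {self.name!r}: population must be > 0, got {self.population!r}"
            )

    @property
    def mass(self) -> float:
        """Cube root of the P*H*G product — the province's 'quality' term."""
        return float(np.cbrt(self.P * self.H * self.G))


@dataclass(frozen=True)
class ProvinceTable:
    """Ordered collection of provinces; order fixes matrix row/column order."""

    records: tuple[ProvinceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise InvalidSizeError(
                f"a province table needs at least 2 records, got {len(self.records)}"
            )
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicated province name(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProvinceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ProvinceRecord:
        return self.records[i]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.records)

    def has_coordinates(self) -> bool:
        return all(r.x is not None and r.y is not None for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        """Canonical DataFrame form (columns as in the CSV schema)."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "name": r.name,
                    "P": r.P,
                    "H": r.H,
                    "G": r.G,
                    "g": r.g,
                    "R": int(r.R),
                    "population": np.nan if r.population is None else r.population,
                    "x": np.nan if r.x is None else r.x,
                    "y": np.nan if r.y is None else r.y,
                }
            )
        return pd.DataFrame(rows, columns=list(PROVINCE_COLUMNS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ProvinceTable":
        missing = {"name", "P", "H", "G", "g", "R"} - set(frame.columns)
        if missing:
            raise SchemaError(f"province table missing column(s): {sorted(missing)}")
        records = []
        for _, row in frame.iterrows():
            kwargs = {}
            for opt in ("population", "x", "y"):
                if opt in frame.columns and pd.notna(row[opt]):
                    kwargs[opt] = float(row[opt])
            for col in ("P", "H", "G", "g"):
                if not np.isfinite(pd.to_numeric(row[col], errors="coerce")):
                    raise SchemaError(
                        f"province {row['name']!r}: non-numeric value in column {col!r}"
                    )
            records.append(
                ProvinceRecord(
                    name=str(row["name"]),
                    P=float(row["P"]),
                    H=float(row["H"]),
                    G=float(row["G"]),
                    g=float(row["g"]),
                    R=int(row["R"]),
                    **kwargs,
                )
            )
        return cls(tuple(records))


def _check_square(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise SchemaError(f"{what} must be square, got shape {values.shape}")
    return values


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric inter-capital distances; zero diagonal, positive off-diagonal."""

    names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = _check_square(self.values, "distance matrix")
        object.__setattr__(self, "values", values)
        n = values.shape[0]
        if len(self.names) != n:
            raise SchemaError(
                f"distance matrix has {n} rows but {len(self.names)} names"
            )
        if not np.allclose(np.diag(values), 0.0):
            raise SchemaError("distance matrix diagonal must be zero")
        asym = np.argwhere(~np.isclose(values, values.T, rtol=1e-12, atol=0.0))
        if asym.size:
            i, j = asym[0]
            raise SchemaError(
                f"distance matrix asymmetric at pair ({self.names[i]!r}, {self.names[j]!r}): "
                f"{values[i, j]!r} != {values[j, i]!r}"
            )
        off = ~np.eye(n, dtype=bool)
        if not np.all(values[off] > 0):
            i, j = np.argwhere(off & (values <= 0))[0]
            raise SchemaError(
                f"off-diagonal distance must be > 0; "
                f"({self.names[i]!r}, {self.names[j]!r}) = {values[i, j]!r}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.names), columns=list(self.names))


@dataclass(frozen=True)
class GravityMatrix:
    """Directed gravity values Y_ij; zero diagonal, finite nonnegative entries."""

    names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = _check_square(self.values, "gravity matrix")
        object.__setattr__(self, "values", values)
        if len(self.names) != values.shape[0]:
            raise SchemaError("gravity matrix size does not match province names")
        if not np.allclose(np.diag(values), 0.0):
            raise SchemaError("gravity matrix diagonal must be zero")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise SchemaError("gravity values must be finite and >= 0")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.names), columns=list(self.names))


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Directed binary network m_ij; the arc i->j means province i's health
    economy is oriented toward province j (patient outflow direction)."""

    names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = _check_square(self.values, "adjacency matrix")
        values = values.astype(int)
        object.__setattr__(self, "values", values)
        if len(self.names) != values.shape[0]:
            raise SchemaError("adjacency matrix size does not match province names")
        if not np.all((values == 0) | (values == 1)):
            raise SchemaError("adjacency entries must be 0 or 1")
        if np.any(np.diag(values) != 0):
            raise SchemaError("adjacency diagonal must be zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_arcs(self) -> int:
        return int(self.values.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.names), columns=list(self.names))

    def edge_list(self) -> pd.DataFrame:
        """Two-column (source, target) directed edge list."""
        src, tgt = np.nonzero(self.values)
        return pd.DataFrame(
            {
                "source": [self.names[i] for i in src],
                "target": [self.names[j] for j in tgt],
            }
        )


def adjacency_from_names(
    names: Sequence[str], arcs: Sequence[tuple[str, str]]
) -> AdjacencyMatrix:
    """Build an adjacency matrix from named arcs (convenience for tests/examples)."""
    idx = {n: i for i, n in enumerate(names)}
    values = np.zeros((len(names), len(names)), dtype=int)
    for a, b in arcs:
        values[idx[a], idx[b]] = 1
    return AdjacencyMatrix(tuple(names), values)
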