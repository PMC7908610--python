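"""CSV and graph-format I/O for province tables, matrices and reports.

All tabular artifacts are CSV with a header row and provinces keyed by
name; square matrices carry the province names as both header and first
column. Numeric round-trips are lossless at 15 significant digits.
Report CSVs round percentages to 3 decimals and [0,1] indices to 4,
matching the precision of the published tables.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SchemaError
from .types import AdjacencyMatrix, DistanceMatrix, GravityMatrix, ProvinceTable

FLOAT_FORMAT = "%.15g"


def read_province_table(path: str | Path) -> ProvinceTable:
    """Read a province attribute table (columns name,P,H,G,g,R[,population,x,y])."""
    frame = pd.read_csv(path)
    return ProvinceTable.from_frame(frame)


def write_province_table(table: ProvinceTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _read_square(path: str | Path, what: str) -> tuple[tuple[str, ...], np.ndarray]:
    frame = pd.read_csv(path, index_col=0)
    names = tuple(str(n) for n in frame.index)
    if tuple(str(c) for c in frame.columns) != names:
        raise SchemaError(f"{what}: header and first column must list the same provinces")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise SchemaError(f"{what}: non-numeric cell ({exc})") from exc
    return names, values


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a symmetric distance matrix CSV (names as header and first column)."""
    names, values = _read_square(path, "distance matrix")
    return DistanceMatrix(names, values)


def write_distance_matrix(D: DistanceMatrix, path: str | Path) -> None:
    D.to_frame().to_csv(path, float_format=FLOAT_FORMAT)


def read_gravity_matrix(path: str | Path) -> GravityMatrix:
    names, values = _read_square(path, "gravity matrix")
    return GravityMatrix(names, values)


def write_gravity_matrix(Y: GravityMatrix, path: str | Path) -> None:
    Y.to_frame().to_csv(path, float_format=FLOAT_FORMAT)


def read_adjacency_matrix(path: str | Path) -> AdjacencyMatrix:
    names, values = _read_square(path, "adjacency matrix")
    return AdjacencyMatrix(names, values)


def write_adjacency_matrix(A: AdjacencyMatrix, path: str | Path) -> None:
    A.to_frame().to_csv(path)


def write_edge_list(A: AdjacencyMatrix, path: str | Path) -> None:
    """Two-column (source,target) directed edge list."""
    A.edge_list().to_csv(path, index=False)


def write_graphml(A: AdjacencyMatrix, path: str | Path) -> None:
    """GraphML export of the directed network for external visualization."""
    G = nx.from_numpy_array(A.values, create_using=nx.DiGraph)
    G = nx.relabel_nodes(G, dict(enumerate(A.names)))
    for _, _, data in G.edges(data=True):
        data.pop("weight", None)
    nx.write_graphml(G, path)
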