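"""Whole-network structure indices and per-province centrality measures.

Whole-network indices are Krackhardt's graph-theoretical dimensions, each
in [0, 1]:

* **density** — fraction of possible ordered ties present, L / (N(N-1));
* **connectedness** — 1 - V / (N(N-1)/2), with V the number of unordered
  node pairs not joined by any path in the underlying undirected graph;
* **hierarchy** — 1 - (symmetrically reachable ordered pairs) /
  (reachable ordered pairs), on directed reachability; 0 when every
  reachable pair is mutually reachable (e.g. cycles), 1 for an out-tree;
* **efficiency** — 1 - M / max(M) on the underlying undirected graph,
  where M counts edges beyond a spanning tree in each component.

Ego measures follow the classic percent normalizations: degree centrality
is 100 * (distinct alters) / (N-1); closeness is 100 * (N-1) / (sum of
geodesic distances); betweenness is the percent share of geodesic
brokerage with denominator (N**2 - 3N + 2) / 2 in the default symmetrized
mode. Provinces are classed as *benefit* (in-degree > out-degree, net
attractors of patients), *spillover* (out > in, net senders) or *balance*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidSizeError
from .types import AdjacencyMatrix

Mode = Literal["symmetrized", "directed"]


@dataclass(frozen=True)
class NetworkSummary:
    """Whole-network characteristics (Table-1-style row)."""

    n_nodes: int
    n_arcs: int
    density: float
    connectedness: float
    hierarchy: float
    efficiency: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "network_size": self.n_nodes,
                    "n_relationships": self.n_arcs,
                    "density": self.density,
                    "connectedness": self.connectedness,
                    "hierarchy": self.hierarchy,
                    "efficiency": self.efficiency,
                }
            ]
        )


def _digraph(A: AdjacencyMatrix) -> nx.DiGraph:
    G = nx.from_numpy_array(A.values, create_using=nx.DiGraph)
    return nx.relabel_nodes(G, dict(enumerate(A.names)))


def network_summary(A: AdjacencyMatrix) -> NetworkSummary:
    """Density, connectedness, hierarchy and efficiency of the network."""
    n = A.n
    if n < 2:
        raise InvalidSizeError("network indices need at least 2 nodes")
    L = A.n_arcs
    density = L / (n * (n - 1))

    G = _digraph(A)
    U = G.to_undirected()

    # connectedness: fraction of unordered pairs joined by an undirected path
    unreachable_pairs = 0
    components = [set(c) for c in nx.connected_components(U)]
    for idx, comp in enumerate(components):
        for other in components[idx + 1 :]:
            unreachable_pairs += len(comp) * len(other)
    connectedness = 1.0 - unreachable_pairs / (n * (n - 1) / 2)

    # hierarchy: 1 - symmetric reachable ordered pairs / reachable ordered pairs
    reach = {v: nx.descendants(G, v) for v in G}
    reachable = sum(len(r) for r in reach.values())
    symmetric = sum(
        1 for v, r in reach.items() for w in r if v in reach[w]
    )
    hierarchy = 0.0 if reachable == 0 else 1.0 - symmetric / reachable

    # efficiency: surplus undirected edges beyond a spanning forest
    extra = 0
    max_extra = 0
    for comp in components:
        n_c = len(comp)
        e_c = U.subgraph(comp).number_of_edges()
        extra += e_c - (n_c - 1)
        max_extra += n_c * (n_c - 1) // 2 - (n_c - 1)
    efficiency = 1.0 if max_extra == 0 else 1.0 - extra / max_extra

    return NetworkSummary(n, L, density, connectedness, hierarchy, efficiency)


def degree_table(A: AdjacencyMatrix) -> pd.DataFrame:
    """Out-degree, in-degree, percent degree centrality and benefit status.

    Degree centrality counts *distinct* alters (union of out- and
    in-neighborhoods) over N-1, so a province tied to the same partner in
    both directions is not counted twice.
    """
    n = A.n
    values = A.values
    out_degree = values.sum(axis=1)
    in_degree = values.sum(axis=0)
    alters = ((values + values.T) > 0).sum(axis=1)
    centrality = 100.0 * alters / (n - 1)
    status = np.where(
        in_degree > out_degree,
        "benefit",
        np.where(out_degree > in_degree, "spillover", "balance"),
    )
    return pd.DataFrame(
        {
            "province": list(A.names),
            "out_degree": out_degree.astype(int),
            "in_degree": in_degree.astype(int),
            "degree_centrality": centrality,
            "benefit_status": status,
        }
    )


def benefit_classification(A: AdjacencyMatrix) -> dict[str, str]:
    """Per-province benefit/balance/spillover labels from in vs out degree."""
    table = degree_table(A)
    return dict(zip(table["province"], table["benefit_status"]))


def _geodesic_graph(A: AdjacencyMatrix, mode: Mode) -> nx.Graph | nx.DiGraph:
    if mode == "symmetrized":
        return _digraph(A).to_undirected()
    if mode == "directed":
        return _digraph(A)
    raise ConfigurationError(f"unknown centrality mode {mode!r}")


def closeness_centrality(A: AdjacencyMatrix, mode: Mode = "symmetrized") -> pd.Series:
    """Percent closeness 100*(N-1)/sum_j d_ij per province.

    A province with any unreachable alter (in the chosen mode) gets NaN:
    its closeness is undefined rather than silently rescaled, because the
    measure is meant for a connected network.
    """
    G = _geodesic_graph(A, mode)
    n = A.n
    out = {}
    for v in A.names:
        dist = nx.single_source_shortest_path_length(G, v)
        if len(dist) < n:
            out[v] = math.nan
        else:
            total = sum(d for w, d in dist.items() if w != v)
            out[v] = 100.0 * (n - 1) / total
    return pd.Series(out, name="closeness_centrality")


def betweenness_centrality(A: AdjacencyMatrix, mode: Mode = "symmetrized") -> pd.Series:
    """Percent betweenness: share of geodesics brokered by each province.

    In symmetrized mode the normalization is 2/(N**2 - 3N + 2) over
    unordered pairs; in directed mode it is 1/((N-1)(N-2)) over ordered
    pairs. Unreachable pairs contribute zero brokerage.
    """
    G = _geodesic_graph(A, mode)
    bc = nx.betweenness_centrality(G, normalized=True)
    return pd.Series({v: 100.0 * bc[v] for v in A.names}, name="betweenness_centrality")


def _dense_rank(values: pd.Series, decimals: int = 3) -> pd.Series:
    """Dense descending rank on values rounded to printing precision,
    so provinces that print identically share a rank. Undefined values
    (NaN closeness on a disconnected network) get rank 0."""
    ranks = values.round(decimals).rank(method="dense", ascending=False)
    return ranks.fillna(0).astype(int)


def centrality_table(A: AdjacencyMatrix, mode: Mode = "symmetrized") -> pd.DataFrame:
    """Full per-province centrality report (Table-2-style).

    Columns: out/in degree, percent degree centrality with dense rank,
    percent closeness and betweenness with dense ranks, and the
    benefit/balance/spillover status.
    """
    table = degree_table(A)
    table["degree_rank"] = _dense_rank(table["degree_centrality"])
    closeness = closeness_centrality(A, mode)
    between = betweenness_centrality(A, mode)
    table["closeness_centrality"] = closeness.loc[table["province"]].to_numpy()
    table["closeness_rank"] = _dense_rank(table["closeness_centrality"])
    table["betweenness_centrality"] = between.loc[table["province"]].to_numpy()
    table["betweenness_rank"] = _dense_rank(table["betweenness_centrality"])
    return table[
        [
            "province",
            "out_degree",
            "in_degree",
            "degree_centrality",
            "benefit_status",
            "degree_rank",
            "closeness_centrality",
            "closeness_rank",
            "betweenness_centrality",
            "betweenness_rank",
        ]
    ]
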