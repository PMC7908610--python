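"""Packaged reference tables for China's 2017 provincial health economy.

Four small CSV fixtures transcribe the published per-province centrality
table, the block spillover accounting, the inter-block density/image
matrices and the population/health-services table for the 2017
31-province network; a fifth records the published four-block
membership. The raw yearbook inputs behind them were never deposited,
so the fixtures are the study's only machine-readable ground truth.

:func:`reconstructed_network` rebuilds a concrete 31-node directed
network that is *consistent with* the published block-level accounting:
the inter-block densities, multiplied by each block pair's arc capacity,
recover integer arc counts (209 in total) that match the published
send/receive totals exactly. Within each block pair the individual arcs
are placed deterministically in lexicographic order — the true
province-to-province arcs were not published — so block-level statistics
are faithful while path-based (hierarchy/efficiency/centrality) values
are not.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .types import AdjacencyMatrix

FIXTURES = {
    "centrality_table": "centrality_table.csv",
    "block_table": "block_table.csv",
    "block_density": "block_density.csv",
    "population_health": "population_health.csv",
    "block_membership": "block_membership.csv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture by name.

    Names: ``centrality_table``, ``block_table``, ``block_density``,
    ``population_health``, ``block_membership``. Province-keyed tables
    are indexed by province name.
    """
    if name not in FIXTURES:
        raise ConfigurationError(
            f"unknown fixture {name!r}; expected one of {sorted(FIXTURES)}"
        )
    with resources.files("healthnet.data").joinpath(FIXTURES[name]).open("r") as fh:
        frame = pd.read_csv(fh)
    if "province" in frame.columns:
        frame = frame.set_index("province")
    return frame


def block_arc_counts() -> tuple[pd.DataFrame, np.ndarray]:
    """Published block membership plus the implied block-to-block arc counts.

    Returns the membership frame and a 4x4 integer matrix of arc counts
    obtained by multiplying each published inter-block density by the
    block pair's capacity and rounding; the row/column sums reproduce the
    published send/receive totals and the grand total of 209 arcs.
    """
    membership = load_fixture("block_membership")
    density = load_fixture("block_density")
    sizes = membership["block"].value_counts().sort_index().to_numpy()
    D = density[[f"density_{b}" for b in (1, 2, 3, 4)]].to_numpy()
    capacity = np.outer(sizes, sizes)
    np.fill_diagonal(capacity, sizes * (sizes - 1))
    return membership, np.rint(D * capacity).astype(int)


def reconstructed_network(seed: int | None = None) -> AdjacencyMatrix:
    """A 31-province digraph realizing the published block-level arc counts.

    Arcs within each (source block, target block) cell are assigned to
    the lexicographically first eligible province pairs (or shuffled with
    ``seed`` before filling, which preserves all block-level counts).
    """
    membership, counts = block_arc_counts()
    names = list(membership.index)
    block_of = membership["block"].to_dict()
    members = {b: [p for p in names if block_of[p] == b] for b in (1, 2, 3, 4)}
    idx = {p: i for i, p in enumerate(names)}

    rng = np.random.default_rng(seed) if seed is not None else None
    values = np.zeros((31, 31), dtype=int)
    for a in (1, 2, 3, 4):
        for b in (1, 2, 3, 4):
            pairs = [
                (i, j)
                for i in members[a]
                for j in members[b]
                if i != j
            ]
            if rng is not None:
                rng.shuffle(pairs)
            for i, j in pairs[: counts[a - 1, b - 1]]:
                values[idx[i], idx[j]] = 1
    return AdjacencyMatrix(tuple(names), values)
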