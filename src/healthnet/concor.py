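"""CONCOR blockmodeling and block-level spillover accounting.

CONCOR (CONvergence of iterated CORrelations) groups structurally
equivalent nodes: each node's profile is its row and column of the
adjacency (diagonal removed), profiles are correlated, and the
correlation matrix is itself repeatedly correlated until every
off-diagonal entry is (within a tolerance) +1 or -1. The sign pattern
then splits the nodes in two; recursing on each part up to a maximum
depth yields up to 2**depth blocks.

Block accounting mirrors the benefit/spillover reading of the network:
for each block we tally arcs received/sent inside vs outside the block,
compare the *actual* share of internal sends with the share *expected*
if ties were spread uniformly (100*(n_b - 1)/(N - 1)), and assign one of
four roles — net beneficial, bidirectional spillover, broker, net
spillover. The role rule is a codified heuristic (see
:func:`classify_block_roles`); explicit per-block overrides are
supported because adjacent role boundaries can be genuinely ambiguous.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .types import AdjacencyMatrix

logger = logging.getLogger(__name__)

ROLES = ("net_beneficial", "bidirectional_spillover", "broker", "net_spillover")


def _profile_correlation(M: np.ndarray) -> np.ndarray:
    """Initial CONCOR correlations between node profiles.

    Node i's profile is its row and column of M. For each pair (i, j) the
    correlation is computed over the coordinates not involving i or j
    (diagonal entries and the mutual ties are excluded *pairwise*, which
    keeps the measure invariant to node relabeling), so the profiles
    compared are [row_i, col_i] vs [row_j, col_j] restricted to the other
    n-2 nodes. Zero-variance profiles correlate 0.
    """
    n = M.shape[0]
    C = np.eye(n)
    flat = 0
    for i in range(n):
        for j in range(i + 1, n):
            keep = [k for k in range(n) if k != i and k != j]
            u = np.concatenate([M[i, keep], M[keep, i]])
            v = np.concatenate([M[j, keep], M[keep, j]])
            if u.std() == 0 or v.std() == 0:
                flat += 1
                r = 0.0
            else:
                r = float(np.corrcoef(u, v)[0, 1])
            C[i, j] = C[j, i] = r
    if flat:
        warnings.warn(
            f"{flat} node pair(s) with a zero-variance profile; correlations set to 0",
            stacklevel=3,
        )
    return C


def _safe_corrcoef(X: np.ndarray) -> np.ndarray:
    """Pearson correlations of the rows of X; zero-variance rows correlate 0."""
    sd = X.std(axis=1)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} zero-variance profile(s); their correlations are set to 0",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 1.0)
    return C


def concor_split(
    M: np.ndarray, criterion: float = 0.2, max_iter: int = 25
) -> tuple[list[int], list[int]]:
    """One CONCOR bipartition of the nodes of a square matrix.

    Iterates ``C <- corrcoef(C)`` starting from the profile correlation
    matrix until every off-diagonal entry is within ``criterion`` of +-1
    (i.e. ``|c| >= 1 - criterion``) or ``max_iter`` is reached, then
    partitions by the sign of the first row. Returns the two index lists
    (the first always contains node 0); the second list is empty when no
    split emerges.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise SchemaError(f"CONCOR needs a square matrix, got shape {M.shape}")
    n = M.shape[0]
    if n < 2:
        raise SchemaError("CONCOR needs at least 2 nodes")

    C = _profile_correlation(M)
    off = ~np.eye(n, dtype=bool)
    for _ in range(max_iter):
        if np.all(np.abs(C[off]) >= 1.0 - criterion):
            break
        C = _safe_corrcoef(C)

    positive = [j for j in range(n) if C[0, j] >= 0]
    negative = [j for j in range(n) if C[0, j] < 0]
    return positive, negative


@dataclass(frozen=True)
class BlockPartition:
    """Node-to-block assignment from recursive CONCOR splitting.

    ``assignments`` maps each node name to a block id, contiguous from 1
    in split (depth-first) order; ``split_tree`` records the nested
    bipartitions as lists of node names.
    """

    assignments: dict[str, int]
    depth: int
    split_tree: list = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return max(self.assignments.values())

    def members(self, block: int) -> list[str]:
        return [v for v, b in self.assignments.items() if b == block]

    def block_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for b in self.assignments.values():
            sizes[b] = sizes.get(b, 0) + 1
        return dict(sorted(sizes.items()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"province": list(self.assignments), "block": list(self.assignments.values())}
        )


def concor_partition(
    A: AdjacencyMatrix,
    depth: int = 2,
    criterion: float = 0.2,
    max_iter: int = 25,
) -> BlockPartition:
    """Recursive CONCOR partition of a directed network into <= 2**depth blocks.

    Each part is re-split on the submatrix of the original adjacency
    restricted to its members, until the requested depth is reached, a
    part has fewer than 2 members, or a split fails to separate anyone.
    """
    if depth < 1:
        raise SchemaError(f"depth must be >= 1, got {depth}")

    names = list(A.names)
    values = A.values.astype(float)
    leaves: list[list[int]] = []

    def recurse(indices: list[int], level: int) -> list:
        if level == 0 or len(indices) < 2:
            leaves.append(indices)
            return [names[i] for i in indices]
        sub = values[np.ix_(indices, indices)]
        pos, neg = concor_split(sub, criterion=criterion, max_iter=max_iter)
        if not neg:  # no separation: keep the part whole
            leaves.append(indices)
            return [names[i] for i in indices]
        left = [indices[k] for k in pos]
        right = [indices[k] for k in neg]
        return [recurse(left, level - 1), recurse(right, level - 1)]

    tree = recurse(list(range(len(names))), depth)
    assignments = {
        names[i]: block_id
        for block_id, leaf in enumerate(leaves, start=1)
        for i in leaf
    }
    # keep the original node order in the mapping
    assignments = {name: assignments[name] for name in names}
    logger.info(
        "CONCOR depth=%d criterion=%.3g -> %d block(s) with sizes %s",
        depth,
        criterion,
        len(leaves),
        [len(leaf) for leaf in leaves],
    )
    return BlockPartition(assignments=assignments, depth=depth, split_tree=tree)


def block_spillover_table(
    A: AdjacencyMatrix,
    part: BlockPartition,
    *,
    theta: float = 2.0,
    rho: float = 0.3,
    role_overrides: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Per-block relation accounting and role labels (Table-3-style).

    For block b with n_b members in an N-node network with the arcs
    tallied inside/outside the block:

    * ``expected_ratio`` = 100 * (n_b - 1) / (N - 1) — internal share of a
      member's ties if ties ignored block structure;
    * ``actual_ratio`` = 100 * send_inside / (send_inside + send_outside).

    Roles come from :func:`classify_block_roles` unless overridden.
    """
    missing = set(A.names) - set(part.assignments)
    if missing:
        raise SchemaError(f"partition does not cover node(s): {sorted(missing)}")
    n = A.n
    blocks = sorted(set(part.assignments.values()))
    membership = np.array([part.assignments[name] for name in A.names])

    rows = []
    for b in blocks:
        mask = membership == b
        n_b = int(mask.sum())
        if n_b == 0:
            warnings.warn(f"block {b} is empty; excluded from the spillover table")
            continue
        inside = int(A.values[np.ix_(mask, mask)].sum())
        send_outside = int(A.values[np.ix_(mask, ~mask)].sum())
        receive_outside = int(A.values[np.ix_(~mask, mask)].sum())
        sends = inside + send_outside
        rows.append(
            {
                "block": b,
                "n_members": n_b,
                "receive_inside": inside,
                "receive_outside": receive_outside,
                "send_inside": inside,
                "send_outside": send_outside,
                "expected_ratio": 100.0 * (n_b - 1) / (n - 1),
                "actual_ratio": 100.0 * inside / sends if sends else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    table["role"] = classify_block_roles(table, theta=theta, rho=rho)
    if role_overrides:
        for b, role in role_overrides.items():
            if role not in ROLES:
                raise SchemaError(f"unknown role {role!r}; expected one of {ROLES}")
            table.loc[table["block"] == int(b), "role"] = role
    return table


def classify_block_roles(
    table: pd.DataFrame, *, theta: float = 2.0, rho: float = 0.3
) -> list[str]:
    """Heuristic four-way role rule on a block accounting table.

    With E the expected ratio, Ax the actual ratio, r = receive_outside
    and s = send_outside:

    * Ax >= E and r > theta*s            -> net_beneficial
    * Ax >= E and r, s both above the
      mean external flow across blocks   -> bidirectional_spillover
    * Ax <  E and r >= rho*s             -> broker
    * otherwise                          -> net_spillover

    The thresholds theta (receive dominance) and rho (minimum brokerage
    return flow) are tunable; blocks near a boundary may legitimately be
    read either way, which is why per-block overrides exist.
    """
    mean_external = (
        (table["receive_outside"].to_numpy() + table["send_outside"].to_numpy()).sum()
        / (2 * len(table))
        if len(table)
        else 0.0
    )
    roles = []
    for _, row in table.iterrows():
        E, Ax = row["expected_ratio"], row["actual_ratio"]
        r, s = row["receive_outside"], row["send_outside"]
        if Ax >= E and r > theta * s:
            roles.append("net_beneficial")
        elif Ax >= E and r > mean_external and s > mean_external:
            roles.append("bidirectional_spillover")
        elif Ax < E and r >= rho * s:
            roles.append("broker")
        else:
            roles.append("net_spillover")
    return roles


@dataclass(frozen=True)
class BlockDensityImage:
    """Inter-block density matrix, its thresholded image, and a fit statistic."""

    blocks: tuple[int, ...]
    density: np.ndarray = field(repr=False)
    image: np.ndarray = field(repr=False)
    cutoff: float
    fit_r2: float

    def density_frame(self) -> pd.DataFrame:
        labels = [f"block_{b}" for b in self.blocks]
        return pd.DataFrame(self.density, index=labels, columns=labels)

    def image_frame(self) -> pd.DataFrame:
        labels = [f"block_{b}" for b in self.blocks]
        return pd.DataFrame(self.image, index=labels, columns=labels)


def block_density_image(
    A: AdjacencyMatrix,
    part: BlockPartition,
    cutoff: float | None = None,
) -> BlockDensityImage:
    """Block-to-block densities thresholded into a 0/1 image matrix.

    density[a][b] is the realized fraction of possible arcs from block a
    to block b (n_a*n_b off-diagonal, n_a*(n_a-1) on the diagonal). The
    image is 1 where density strictly exceeds the cutoff, which defaults
    to the whole-network density. ``fit_r2`` is the squared Pearson
    correlation between the off-diagonal adjacency entries and the
    density of their block pair — a blockmodel goodness-of-fit.
    """
    if cutoff is None:
        n = A.n
        cutoff = A.n_arcs / (n * (n - 1))
    blocks = tuple(sorted(set(part.assignments.values())))
    membership = np.array([part.assignments[name] for name in A.names])
    B = len(blocks)
    density = np.zeros((B, B))
    for a_pos, a in enumerate(blocks):
        for b_pos, b in enumerate(blocks):
            mask_a = membership == a
            mask_b = membership == b
            n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
            capacity = n_a * (n_a - 1) if a == b else n_a * n_b
            if capacity == 0:
                warnings.warn(
                    f"block {a} is a singleton; its internal density is undefined, reported as 0"
                )
                density[a_pos, b_pos] = 0.0
            else:
                arcs = int(A.values[np.ix_(mask_a, mask_b)].sum())
                density[a_pos, b_pos] = arcs / capacity
    image = (density > cutoff).astype(int)

    # goodness of fit: correlate observed off-diagonal arcs with the
    # density predicted for each ordered pair's block pair
    pos_of = {b: k for k, b in enumerate(blocks)}
    n = A.n
    off = ~np.eye(n, dtype=bool)
    predicted = density[
        np.ix_(
            [pos_of[b] for b in membership],
            [pos_of[b] for b in membership],
        )
    ]
    obs = A.values[off].astype(float)
    pred = predicted[off]
    if obs.std() == 0 or pred.std() == 0:
        fit_r2 = 0.0
    else:
        fit_r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    return BlockDensityImage(
        blocks=blocks, density=density, image=image, cutoff=float(cutoff), fit_r2=fit_r2
    )
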