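"""CONCOR splitting, block accounting, and density/image matrices."""

import numpy as np
import pandas as pd
import pytest

from conftest import adjacency, planted_bipartition, planted_hierarchy, random_digraph

from healthnet.concor import (
    BlockPartition,
    block_density_image,
    block_spillover_table,
    classify_block_roles,
    concor_partition,
    concor_split,
)
from healthnet.errors import SchemaError


def as_sets(indices_a, indices_b):
    return {frozenset(indices_a), frozenset(indices_b)}


def test_split_recovers_two_perfect_cliques():
    values = np.zeros((6, 6), dtype=int)
    values[:3, :3] = 1
    values[3:, 3:] = 1
    np.fill_diagonal(values, 0)
    pos, neg = concor_split(values)
    assert as_sets(pos, neg) == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}


def test_split_recovers_planted_bipartition():
    values, labels = planted_bipartition(20, p_in=0.9, p_out=0.05, seed=11)
    pos, neg = concor_split(values)
    planted = {frozenset(np.nonzero(labels == 0)[0]), frozenset(np.nonzero(labels == 1)[0])}
    assert as_sets(pos, neg) == planted


def test_split_converges_within_criterion(rng):
    values = (rng.uniform(size=(12, 12)) < 0.4).astype(float)
    np.fill_diagonal(values, 0)
    # re-run the iteration exactly as concor_split does, then check the
    # advertised postcondition on the converged matrix
    from healthnet.concor import _profile_correlation, _safe_corrcoef

    C = _profile_correlation(values)
    off = ~np.eye(12, dtype=bool)
    for _ in range(25):
        if np.all(np.abs(C[off]) >= 0.8):
            break
        C = _safe_corrcoef(C)
    assert np.all(np.abs(C[off]) >= 0.8)


def test_split_rejects_bad_shapes():
    with pytest.raises(SchemaError):
        concor_split(np.zeros((2, 3)))
    with pytest.raises(SchemaError):
        concor_split(np.zeros((1, 1)))


def test_partition_depth_one_is_single_split(rng):
    A = random_digraph(10, 0.4, rng)
    pos, neg = concor_split(A.values.astype(float))
    part = concor_partition(A, depth=1)
    got = {frozenset(v for v, b in part.assignments.items() if b == blk)
           for blk in set(part.assignments.values())}
    expected = {
        frozenset(A.names[i] for i in pos),
        frozenset(A.names[i] for i in neg),
    }
    assert got == expected


def test_partition_respects_block_bound(rng):
    for depth in (1, 2, 3):
        A = random_digraph(14, 0.3, rng)
        part = concor_partition(A, depth=depth)
        assert part.n_blocks <= 2**depth
        assert sorted(set(part.assignments.values())) == list(
            range(1, part.n_blocks + 1)
        )


def test_partition_recovers_nested_hierarchy():
    A, labels = planted_hierarchy(seed=5)
    part = concor_partition(A, depth=2)
    got = {
        frozenset(int(v[1:]) for v, b in part.assignments.items() if b == blk)
        for blk in set(part.assignments.values())
    }
    planted = {frozenset(range(5 * k, 5 * k + 5)) for k in range(4)}
    assert got == planted


def test_partition_invariant_to_relabeling(rng):
    """On a convergent (structured) input, relabeling the nodes permutes
    the recovered blocks but does not change them as sets."""
    A, _ = planted_hierarchy(seed=2)
    part = concor_partition(A, depth=2)
    perm = rng.permutation(20)
    from healthnet.types import AdjacencyMatrix

    A2 = AdjacencyMatrix(
        tuple(A.names[i] for i in perm), A.values[np.ix_(perm, perm)]
    )
    part2 = concor_partition(A2, depth=2)
    blocks1 = {
        frozenset(v for v, b in part.assignments.items() if b == blk)
        for blk in set(part.assignments.values())
    }
    blocks2 = {
        frozenset(v for v, b in part2.assignments.items() if b == blk)
        for blk in set(part2.assignments.values())
    }
    assert blocks1 == blocks2


def two_block_fixture():
    """6 nodes in two blocks of 3 with known internal/external arcs."""
    values = np.zeros((6, 6), dtype=int)
    arcs = [(0, 1), (1, 0), (3, 4), (0, 3), (1, 4), (2, 5), (4, 0)]
    for i, j in arcs:
        values[i, j] = 1
    A = adjacency(values)
    part = BlockPartition(
        assignments={A.names[i]: 1 if i < 3 else 2 for i in range(6)}, depth=1
    )
    return A, part


def test_spillover_accounting():
    A, part = two_block_fixture()
    t = block_spillover_table(A, part).set_index("block")
    # block 1: internal (0,1),(1,0); sends (0,3),(1,4),(2,5); receives (4,0)
    assert t.loc[1, "send_inside"] == t.loc[1, "receive_inside"] == 2
    assert t.loc[1, "send_outside"] == 3
    assert t.loc[1, "receive_outside"] == 1
    assert t.loc[1, "expected_ratio"] == pytest.approx(100 * 2 / 5)
    assert t.loc[1, "actual_ratio"] == pytest.approx(100 * 2 / 5)
    # arc conservation across blocks
    assert (t["send_inside"] + t["send_outside"]).sum() == A.n_arcs
    assert (t["receive_inside"] + t["receive_outside"]).sum() == A.n_arcs


def test_spillover_boundary_no_external_sends():
    values = np.zeros((4, 4), dtype=int)
    values[0, 1] = values[1, 0] = 1
    A = adjacency(values)
    part = BlockPartition(
        assignments={A.names[0]: 1, A.names[1]: 1, A.names[2]: 2, A.names[3]: 2},
        depth=1,
    )
    t = block_spillover_table(A, part).set_index("block")
    assert t.loc[1, "actual_ratio"] == pytest.approx(100.0)


def test_role_rule_codification():
    table = pd.DataFrame(
        {
            "block": [1, 2, 3, 4],
            "expected_ratio": [10.0, 10.0, 40.0, 40.0],
            "actual_ratio": [30.0, 20.0, 5.0, 5.0],
            "receive_outside": [50, 30, 20, 2],
            "send_outside": [10, 28, 40, 40],
        }
    )
    roles = classify_block_roles(table)
    assert roles[0] == "net_beneficial"  # receives >> theta * sends
    assert roles[1] == "bidirectional_spillover"  # both flows above average
    assert roles[2] == "broker"  # internal-poor but passes flow back
    assert roles[3] == "net_spillover"  # sends massively, receives almost nothing


def test_roles_can_be_overridden():
    A, part = two_block_fixture()
    t = block_spillover_table(A, part, role_overrides={2: "net_spillover"})
    assert t.set_index("block").loc[2, "role"] == "net_spillover"


def test_density_image_basics():
    A, part = two_block_fixture()
    di = block_density_image(A, part, cutoff=0.2)
    # block 1 internal: 2 arcs of 6 possible
    assert di.density[0, 0] == pytest.approx(2 / 6)
    # block1 -> block2: 3 arcs of 9 possible
    assert di.density[0, 1] == pytest.approx(3 / 9)
    assert di.image[0, 0] == 1 and di.image[1, 1] == 0
    assert 0.0 <= di.fit_r2 <= 1.0


def test_density_image_cutoff_one_blanks_image(rng):
    A = random_digraph(10, 0.5, rng)
    part = concor_partition(A, depth=2)
    di = block_density_image(A, part, cutoff=1.0)
    assert di.image.sum() == 0


def test_singleton_block_density_is_zero_with_warning():
    values = np.zeros((3, 3), dtype=int)
    values[0, 1] = 1
    A = adjacency(values)
    part = BlockPartition(
        assignments={A.names[0]: 1, A.names[1]: 2, A.names[2]: 2}, depth=1
    )
    with pytest.warns(UserWarning, match="singleton"):
        di = block_density_image(A, part, cutoff=0.5)
    assert di.density[0, 0] == 0.0
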