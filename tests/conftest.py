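import numpy as np
import pytest

from healthnet.types import AdjacencyMatrix


def names(n: int) -> tuple[str, ...]:
    return tuple(f"n{i:02d}" for i in range(n))


def adjacency(values: np.ndarray) -> AdjacencyMatrix:
    values = np.asarray(values, dtype=int)
    return AdjacencyMatrix(names(values.shape[0]), values)


def random_digraph(n: int, p: float, rng: np.random.Generator) -> AdjacencyMatrix:
    values = (rng.uniform(size=(n, n)) < p).astype(int)
    np.fill_diagonal(values, 0)
    return adjacency(values)


def planted_bipartition(
    n: int, p_in: float, p_out: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two planted groups of n/2 nodes; returns (adjacency values, labels)."""
    rng = np.random.default_rng(seed)
    labels = np.array([0] * (n // 2) + [1] * (n - n // 2))
    probs = np.where(labels[:, None] == labels[None, :], p_in, p_out)
    values = (rng.uniform(size=(n, n)) < probs).astype(int)
    np.fill_diagonal(values, 0)
    return values, labels


def planted_hierarchy(
    seed: int, p_in: float = 0.9, p_super: float = 0.3, p_out: float = 0.05
) -> tuple[AdjacencyMatrix, np.ndarray]:
    """Four planted groups of five in two super-groups (a 2-level hierarchy)."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1, 2, 3], 5)
    supers = labels // 2
    probs = np.where(
        labels[:, None] == labels[None, :],
        p_in,
        np.where(supers[:, None] == supers[None, :], p_super, p_out),
    )
    values = (rng.uniform(size=(20, 20)) < probs).astype(int)
    np.fill_diagonal(values, 0)
    return adjacency(values), labels


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
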