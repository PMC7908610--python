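"""Hand-rolled brute-force oracles used to cross-check the package.

Everything here is deliberately independent of networkx: distances come
from a plain BFS, geodesic counts from explicit path enumeration over
BFS predecessor sets. Only meant for tiny graphs (N <= ~8).
"""

from collections import deque

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> dict[int, int]:
    """Shortest-path lengths from ``source`` following 1-entries of ``adj``."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in np.nonzero(adj[v])[0]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(int(w))
    return dist


def geodesic_counts(adj: np.ndarray, s: int, t: int) -> tuple[int, dict[int, int]]:
    """Number of s->t geodesics and, per node, how many pass through it
    as an interior vertex. Enumerated explicitly via predecessor DAG walk."""
    dist = bfs_distances(adj, s)
    if t not in dist or s == t:
        return 0, {}
    paths: list[tuple[int, ...]] = []

    def extend(path: tuple[int, ...]) -> None:
        v = path[-1]
        if v == t:
            paths.append(path)
            return
        for w in np.nonzero(adj[v])[0]:
            w = int(w)
            if dist.get(w) == dist[v] + 1 and dist[w] <= dist[t]:
                extend(path + (w,))

    extend((s,))
    paths = [p for p in paths if len(p) - 1 == dist[t]]
    through: dict[int, int] = {}
    for p in paths:
        for v in p[1:-1]:
            through[v] = through.get(v, 0) + 1
    return len(paths), through


def closeness_percent(adj: np.ndarray, directed: bool) -> list[float]:
    """100*(N-1)/sum(d) per node; NaN when any alter is unreachable."""
    n = adj.shape[0]
    use = adj if directed else ((adj + adj.T) > 0).astype(int)
    out = []
    for v in range(n):
        dist = bfs_distances(use, v)
        if len(dist) < n:
            out.append(float("nan"))
        else:
            out.append(100.0 * (n - 1) / sum(d for w, d in dist.items() if w != v))
    return out


def betweenness_percent(adj: np.ndarray, directed: bool) -> list[float]:
    """Percent betweenness with 2/(N^2-3N+2) (undirected) or
    1/((N-1)(N-2)) (directed) normalization, by full path enumeration."""
    n = adj.shape[0]
    use = adj if directed else ((adj + adj.T) > 0).astype(int)
    raw = [0.0] * n
    pairs = (
        [(s, t) for s in range(n) for t in range(n) if s != t]
        if directed
        else [(s, t) for s in range(n) for t in range(s + 1, n)]
    )
    for s, t in pairs:
        total, through = geodesic_counts(use, s, t)
        if total == 0:
            continue
        for v, cnt in through.items():
            raw[v] += cnt / total
    denom = (n - 1) * (n - 2) if directed else (n * n - 3 * n + 2) / 2
    if denom == 0:  # n <= 2: no interior vertices possible
        return [0.0] * n
    return [100.0 * r / denom for r in raw]
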