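"""Independent brute-force oracles for the graph metrics and statistics.

Everything here is deliberately naive (cubic relaxation, exhaustive
triple scans, full shortest-path enumeration, restricted-growth
partition enumeration) and shares no code with the package
implementations it checks.
"""

from itertools import combinations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """Cubic-time all-pairs shortest paths on a 0/1 adjacency."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency_brute(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def path_length_brute(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    vals = [
        d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    ]
    return float(np.mean(vals)) if vals else float("nan")


def clustering_brute(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering by scanning all neighbour pairs."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def local_efficiency_brute(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        total += global_efficiency_brute(adj[np.ix_(nbrs, nbrs)])
    return total / n


def transitivity_brute(adj: np.ndarray) -> float:
    n = adj.shape[0]
    triangles = sum(
        1
        for i, j, k in combinations(range(n), 3)
        if adj[i, j] and adj[j, k] and adj[i, k]
    )
    triples = sum(
        1
        for i in range(n)
        for j, k in combinations([x for x in range(n) if adj[i, x]], 2)
    )
    return 3.0 * triangles / triples if triples else 0.0


def assortativity_brute(adj: np.ndarray) -> float:
    """Plain Pearson correlation over the doubled edge-endpoint list."""
    k = adj.sum(axis=1)
    pairs = [
        (k[i], k[j])
        for i in range(adj.shape[0])
        for j in range(adj.shape[0])
        if i != j and adj[i, j]
    ]  # both orientations included
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if x.size == 0 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def all_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Every shortest s-t path, by DFS over the BFS-layered DAG."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    if not np.isfinite(d[s, t]):
        return []
    paths = []

    def walk(u, acc):
        if u == t:
            paths.append(acc)
            return
        for v in range(n):
            if adj[u, v] and d[v, t] == d[u, t] - 1:
                walk(v, acc + [v])

    walk(s, [s])
    return paths


def betweenness_brute(adj: np.ndarray) -> np.ndarray:
    """B(i) by exhaustive shortest-path enumeration over ordered pairs."""
    n = adj.shape[0]
    out = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for i in range(n):
                if i in (s, t):
                    continue
                through = sum(1 for p in paths if i in p[1:-1])
                out[i] += through / len(paths)
    return out / ((n - 1) * (n - 2))


def set_partitions(n: int):
    """All partitions of range(n) via restricted-growth strings."""
    a = [0] * n
    b = [0] * n  # b[i] = max(a[:i+1])

    def emit():
        k = max(a) + 1
        blocks = [[] for _ in range(k)]
        for i, c in enumerate(a):
            blocks[c].append(i)
        return blocks

    yield emit()
    while True:
        i = n - 1
        while i > 0 and a[i] == b[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        for j in range(i + 1, n):
            a[j] = 0
        for j in range(i, n):
            b[j] = max(b[j - 1], a[j])
        yield emit()


def modularity_q_brute(adj: np.ndarray, blocks: list[list[int]]) -> float:
    """Q via the pairwise sum of (A_ij - k_i k_j / 2m) / 2m."""
    k = adj.sum(axis=1).astype(float)
    two_m = k.sum()
    q = 0.0
    for block in blocks:
        for i in block:
            for j in block:
                q += adj[i, j] - k[i] * k[j] / two_m
    return q / two_m


def modularity_exhaustive(adj: np.ndarray) -> float:
    """Best Q over every partition of the nodes."""
    return max(
        modularity_q_brute(adj, blocks) for blocks in set_partitions(adj.shape[0])
    )


def weighted_pearson_brute(x, y, w) -> float:
    """Direct evaluation of the weighted-moment correlation formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float) / np.sum(w)
    mx = (w * x).sum()
    my = (w * y).sum()
    cov = (w * (x - mx) * (y - my)).sum()
    return cov / np.sqrt((w * (x - mx) ** 2).sum() * (w * (y - my) ** 2).sum())


def random_adjacency(n: int, rng: np.random.Generator, p: float = 0.5) -> np.ndarray:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1).astype(int)
    return adj + adj.T
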