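"""Binarization and topological metrics of windowed connectivity matrices.

Connectivity matrices are thresholded into undirected binary graphs
(absolute, proportional-to-maximum, or wiring-cost rules) and
characterised by global metrics (global efficiency, network local
efficiency, clustering coefficient, average degree, characteristic path
length, their random-network-normalised ratios and the small-world
coefficient, transitivity, assortativity, modularity) and nodal metrics
(nodal efficiency, nodal local efficiency, nodal clustering, degree,
betweenness centrality).

Distances are shortest-path *edge counts*.  Unreachable pairs contribute
zero to efficiencies and are excluded from the characteristic path
length average (a convention that matters at sparse thresholds and is
therefore stated prominently).  All metrics are authored here on plain
adjacency arrays; graph libraries appear only as independent oracles in
the test suite.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .windows import FCSeries

log = logging.getLogger(__name__)

GLOBAL_METRICS = (
    "E_glob",
    "E_network_loc",
    "C_network",
    "avg_degree",
    "L",
    "transitivity",
    "assortativity",
    "modularity_Q",
    "C_norm",
    "L_norm",
    "S",
)
NODAL_METRICS = ("E_nodal", "nodal_local_efficiency", "C", "degree", "betweenness")
DEFAULT_GLOBAL = ("E_glob", "E_network_loc", "C_network", "avg_degree", "L")


class UndefinedMetricError(ValueError):
    """The metric is undefined on this graph (e.g. too few nodes)."""


@dataclass
class BinarizationSpec:
    """How to turn a correlation matrix into a 0/1 adjacency.

    ``method``:

    - ``"absolute"``: edge iff coefficient > threshold (threshold in [-1, 1]);
    - ``"proportional"``: edge iff coefficient > threshold x max
      off-diagonal coefficient of that matrix (threshold in [0, 1]);
    - ``"cost"``: keep the top ``round(threshold * n(n-1)/2)`` off-diagonal
      values (threshold in [0, 1]).

    ``use_abs`` applies the absolute value before any rule.  ``thresholds``
    may be an explicit sequence or a ``(min, max, step)`` sweep.
    """

    method: Literal["absolute", "proportional", "cost"] = "absolute"
    thresholds: Sequence[float] | tuple[float, float, float] = (0.5, 0.85, 0.01)
    sweep: bool = True  # interpret 3-tuple thresholds as (min, max, step)
    use_abs: bool = False

    def threshold_values(self) -> np.ndarray:
        if self.sweep and len(self.thresholds) == 3:
            lo, hi, step = self.thresholds
            n = int(round((hi - lo) / step)) + 1
            vals = lo + step * np.arange(n)
            return vals[vals <= hi + 1e-12]
        return np.asarray(list(self.thresholds), dtype=float)


@dataclass
class BinaryNetwork:
    """Symmetric 0/1 adjacency with zero diagonal."""

    adjacency: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        a = (a != 0).astype(np.int8)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(a, 0)
        self.adjacency = a
        if not self.node_labels:
            self.node_labels = [f"n{i + 1}" for i in range(a.shape[0])]

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def m(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


def binarize(
    fc: np.ndarray,
    spec: BinarizationSpec,
    threshold: float,
    node_labels: list[str] | None = None,
) -> BinaryNetwork:
    """Apply one binarization rule at one threshold.

    Missing entries (NaN) are never kept.  Cost ties are broken by
    descending value then lexicographic node-pair order.
    """
    fc = np.asarray(fc, dtype=float)
    n = fc.shape[0]
    vals = np.abs(fc) if spec.use_abs else fc.copy()
    np.fill_diagonal(vals, np.nan)
    iu, ju = np.triu_indices(n, k=1)
    upper = vals[iu, ju]
    finite = np.isfinite(upper)
    keep = np.zeros(upper.shape, dtype=bool)
    if spec.method == "absolute":
        keep[finite] = upper[finite] > threshold
    elif spec.method == "proportional":
        if finite.any():
            ref = np.nanmax(upper[finite])
            keep[finite] = upper[finite] > threshold * ref
    elif spec.method == "cost":
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("cost threshold must lie in [0, 1]")
        want = int(round(threshold * n * (n - 1) / 2))
        avail = int(finite.sum())
        if want > avail:
            log.warning(
                "cost threshold asks for %d edges but only %d finite "
                "coefficients exist; capping",
                want,
                avail,
            )
            want = avail
        if want > 0:
            # sort by descending value, then by (i, j) for determinism
            order = np.lexsort((ju, iu, -np.where(finite, upper, -np.inf)))
            keep[order[:want]] = True
    else:
        raise ValueError(f"unknown binarization method {spec.method!r}")
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj += adj.T
    return BinaryNetwork(adjacency=adj, node_labels=node_labels or [])


def all_pairs_shortest_paths(g: BinaryNetwork) -> np.ndarray:
    """Shortest-path edge counts by BFS from every node.

    Returns a float matrix with ``inf`` for unreachable pairs and zero
    diagonal.
    """
    n = g.n
    adj_lists = [np.flatnonzero(g.adjacency[i]) for i in range(n)]
    d = np.full((n, n), np.inf)
    for s in range(n):
        d[s, s] = 0.0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj_lists[u]:
                if not np.isfinite(d[s, v]):
                    d[s, v] = d[s, u] + 1
                    q.append(v)
    return d


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        raise UndefinedMetricError("efficiency undefined for n < 2")
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    reach = off & np.isfinite(d)
    inv[reach] = 1.0 / d[reach]
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(g: BinaryNetwork) -> float:
    """Mean of 1/d_ij over ordered node pairs; unreachable pairs give 0."""
    return _efficiency_from_distances(all_pairs_shortest_paths(g))


def _neighbor_subgraph(g: BinaryNetwork, i: int) -> BinaryNetwork:
    nbrs = np.flatnonzero(g.adjacency[i])
    sub = g.adjacency[np.ix_(nbrs, nbrs)]
    return BinaryNetwork(adjacency=sub)


def _nodal_local_efficiency(g: BinaryNetwork) -> np.ndarray:
    out = np.zeros(g.n)
    for i in range(g.n):
        if g.adjacency[i].sum() < 2:
            continue
        out[i] = global_efficiency(_neighbor_subgraph(g, i))
    return out


def network_local_efficiency(g: BinaryNetwork) -> float:
    """Mean over nodes of the efficiency of each neighbour-induced subgraph."""
    if g.n < 1:
        raise UndefinedMetricError("empty graph")
    return float(_nodal_local_efficiency(g).mean())


def clustering(g: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean.

    C(i) = 2 * (triangles through i) / (k_i (k_i - 1)); zero when k_i < 2.
    On binary graphs this equals the cube-root-product triple sum.
    """
    a = g.adjacency.astype(float)
    k = a.sum(axis=1)
    tri2 = np.diag(a @ a @ a)  # 2 * triangles through each node
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(k >= 2, tri2 / (k * (k - 1)), 0.0)
    return c, float(c.mean())


def characteristic_path_length(g: BinaryNetwork) -> float:
    """Mean shortest-path length over *reachable* ordered pairs."""
    d = all_pairs_shortest_paths(g)
    off = ~np.eye(g.n, dtype=bool)
    reach = off & np.isfinite(d)
    if not reach.any():
        raise UndefinedMetricError("no reachable node pair")
    return float(d[reach].mean())


def transitivity(g: BinaryNetwork) -> float:
    """3 x triangles / connected triples; 0 (with warning) when no triple."""
    a = g.adjacency.astype(float)
    k = a.sum(axis=1)
    triangles = np.trace(a @ a @ a) / 6.0
    triples = float((k * (k - 1)).sum()) / 2.0
    if triples == 0:
        log.warning("no connected triples; transitivity set to 0")
        return 0.0
    return float(3.0 * triangles / triples)


def assortativity(g: BinaryNetwork) -> float:
    """Pearson correlation of endpoint degrees over both edge orientations.

    Returns NaN when the endpoint degrees have zero variance (e.g. a
    regular graph).
    """
    iu, ju = np.nonzero(np.triu(g.adjacency, k=1))
    if iu.size == 0:
        return float("nan")
    k = g.degrees().astype(float)
    x = np.concatenate([k[iu], k[ju]])
    y = np.concatenate([k[ju], k[iu]])
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def partition_modularity(g: BinaryNetwork, communities: Sequence[set[int]]) -> float:
    """Newman modularity Q of a node partition."""
    m = g.m
    if m == 0:
        raise UndefinedMetricError("modularity undefined without edges")
    a = g.adjacency
    k = g.degrees()
    q = 0.0
    for comm in communities:
        nodes = sorted(comm)
        lc = a[np.ix_(nodes, nodes)].sum() / 2.0
        dc = float(k[nodes].sum())
        q += lc / m - (dc / (2.0 * m)) ** 2
    return float(q)


def _partitions(items: list[int]):
    """All set partitions (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1 :]
        yield part + [{first}]


def modularity(
    g: BinaryNetwork, seed: int | None = None, method: Literal["greedy", "exact"] = "greedy"
) -> tuple[float, list[set[int]]]:
    """Maximise Newman modularity Q.

    ``"greedy"`` is deterministic agglomerative merging (best positive
    delta-Q, ties broken by lowest community index pair), returning the
    best partition seen along the merge path; ``"exact"`` enumerates all
    partitions and is only feasible for small n.  The returned Q is
    never below the single-module partition's Q = 0.
    """
    m = g.m
    if m == 0:
        raise UndefinedMetricError("modularity undefined without edges")
    if method == "exact":
        best_q, best_part = -np.inf, None
        for part in _partitions(list(range(g.n))):
            q = partition_modularity(g, part)
            if q > best_q + 1e-15:
                best_q, best_part = q, part
        return float(best_q), [set(c) for c in best_part]
    # greedy agglomeration on community aggregates
    comms: dict[int, set[int]] = {i: {i} for i in range(g.n)}
    e = g.adjacency.astype(float).copy()  # inter-community edge counts
    deg = g.degrees().astype(float).copy()
    best_q = partition_modularity(g, list(comms.values()))
    best_part = [set(c) for c in comms.values()]
    while len(comms) > 1:
        ids = sorted(comms)
        best_dq, best_pair = -np.inf, None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                ca, cb = ids[ai], ids[bi]
                if e[ca, cb] == 0:
                    continue
                dq = e[ca, cb] / m - deg[ca] * deg[cb] / (2.0 * m**2)
                if dq > best_dq + 1e-15:
                    best_dq, best_pair = dq, (ca, cb)
        if best_pair is None or best_dq <= 1e-15:
            # no connected merge improves Q; stop
            break
        ca, cb = best_pair
        comms[ca] |= comms.pop(cb)
        e[ca, :] += e[cb, :]
        e[:, ca] += e[:, cb]
        e[cb, :] = 0.0
        e[:, cb] = 0.0
        e[ca, ca] = 0.0
        deg[ca] += deg[cb]
        deg[cb] = 0.0
        q = partition_modularity(g, list(comms.values()))
        if q > best_q + 1e-15:
            best_q = q
            best_part = [set(c) for c in comms.values()]
    single = partition_modularity(g, [set(range(g.n))])
    if single > best_q:
        best_q, best_part = single, [set(range(g.n))]
    return float(best_q), best_part


def betweenness(g: BinaryNetwork) -> np.ndarray:
    """Betweenness centrality by Brandes' algorithm.

    B(i) sums, over ordered pairs (j, k) with j, k != i, the number of
    shortest j-k paths through i divided by the total number of shortest
    j-k paths, normalised by (n-1)(n-2).
    """
    n = g.n
    if n < 3:
        raise UndefinedMetricError("betweenness needs n >= 3")
    adj_lists = [np.flatnonzero(g.adjacency[i]) for i in range(n)]
    raw = np.zeros(n)
    for s in range(n):
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order = []
        q = deque([s])
        while q:
            u = q.popleft()
            order.append(u)
            for v in adj_lists[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    q.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for v in reversed(order):
            for u in preds[v]:
                delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
            if v != s:
                raw[v] += delta[v]
    return raw / ((n - 1) * (n - 2))


@dataclass
class NodalMetrics:
    """Per-node metric arrays, aligned with the network's node order."""

    E_nodal: np.ndarray
    nodal_local_efficiency: np.ndarray
    C: np.ndarray
    degree: np.ndarray
    betweenness: np.ndarray
    node_labels: list[str]


def nodal_metrics(g: BinaryNetwork) -> NodalMetrics:
    """All nodal metrics of a binary network."""
    d = all_pairs_shortest_paths(g)
    n = g.n
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    reach = off & np.isfinite(d)
    inv[reach] = 1.0 / d[reach]
    e_nodal = inv.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)
    c, _ = clustering(g)
    b = betweenness(g) if n >= 3 else np.zeros(n)
    return NodalMetrics(
        E_nodal=e_nodal,
        nodal_local_efficiency=_nodal_local_efficiency(g),
        C=c,
        degree=g.degrees(),
        betweenness=b,
        node_labels=list(g.node_labels),
    )


@dataclass
class RandomEnsemble:
    """Reference ensemble of uniform random (n, m) simple graphs."""

    n: int
    m: int
    size: int
    seed: int
    C_members: np.ndarray
    L_members: np.ndarray

    @property
    def C_rand(self) -> float:
        return float(self.C_members.mean())

    @property
    def L_rand(self) -> float:
        return float(self.L_members.mean())

    def standard_errors(self) -> tuple[float, float]:
        se = lambda x: float(x.std(ddof=1) / np.sqrt(self.size))
        return se(self.C_members), se(self.L_members)


def random_graph(n: int, m: int, rng: np.random.Generator) -> BinaryNetwork:
    """Uniform random simple graph with exactly n nodes and m edges."""
    total = n * (n - 1) // 2
    if m > total:
        raise ValueError(f"cannot place {m} edges among {n} nodes")
    chosen = rng.choice(total, size=m, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[chosen], ju[chosen]] = 1
    adj += adj.T
    return BinaryNetwork(adjacency=adj)


def degree_preserving_random(
    g: BinaryNetwork, rng: np.random.Generator, n_swaps_per_edge: int = 10
) -> BinaryNetwork:
    """Random graph with g's exact degree sequence via edge swaps."""
    adj = g.adjacency.copy()
    edges = list(zip(*np.nonzero(np.triu(adj, k=1))))
    m = len(edges)
    attempts = n_swaps_per_edge * m
    for _ in range(attempts):
        a, b = edges[rng.integers(m)]
        c, d = edges[rng.integers(m)]
        if len({a, b, c, d}) < 4:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges = list(zip(*np.nonzero(np.triu(adj, k=1))))
    return BinaryNetwork(adjacency=adj, node_labels=list(g.node_labels))


def random_ensemble(
    g: BinaryNetwork,
    size: int = 20,
    seed: int = 0,
    method: Literal["uniform", "rewire"] = "uniform",
) -> RandomEnsemble:
    """Generate the null ensemble matched on node and edge counts.

    ``"uniform"`` draws simple graphs uniformly at fixed (n, m);
    ``"rewire"`` preserves the degree sequence by double-edge swaps.
    Deterministic for a fixed seed.
    """
    if g.m < 1:
        raise UndefinedMetricError("cannot build a null ensemble without edges")
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(size):
        r = (
            random_graph(g.n, g.m, rng)
            if method == "uniform"
            else degree_preserving_random(g, rng)
        )
        _, c = clustering(r)
        cs.append(c)
        ls.append(characteristic_path_length(r))
    return RandomEnsemble(
        n=g.n,
        m=g.m,
        size=size,
        seed=seed,
        C_members=np.array(cs),
        L_members=np.array(ls),
    )


def normalized_metrics(
    g: BinaryNetwork, ens: RandomEnsemble
) -> tuple[float, float, float]:
    """(C_norm, L_norm, S): clustering and path length relative to the
    ensemble means, and their ratio (small-world coefficient)."""
    if ens.C_rand <= 0 or ens.L_rand <= 0:
        raise UndefinedMetricError(
            "random ensemble has zero mean clustering or path length"
        )
    _, c = clustering(g)
    l = characteristic_path_length(g)
    c_norm = c / ens.C_rand
    l_norm = l / ens.L_rand
    return c_norm, l_norm, c_norm / l_norm


def global_metrics(
    g: BinaryNetwork,
    ensemble_size: int = 20,
    seed: int = 0,
    which: Iterable[str] = DEFAULT_GLOBAL,
) -> dict[str, float]:
    """Selected global metrics of one binary network.

    Normalised metrics (C_norm, L_norm, S) draw a fresh seeded random
    ensemble; graphs without edges yield NaN for path-based metrics.
    """
    which = list(which)
    out: dict[str, float] = {}
    has_edges = g.m > 0
    for name in which:
        if name in ("C_norm", "L_norm", "S"):
            continue
        try:
            if name == "E_glob":
                out[name] = global_efficiency(g)
            elif name == "E_network_loc":
                out[name] = network_local_efficiency(g)
            elif name == "C_network":
                out[name] = clustering(g)[1]
            elif name == "avg_degree":
                out[name] = float(g.degrees().mean())
            elif name == "L":
                out[name] = characteristic_path_length(g)
            elif name == "transitivity":
                out[name] = transitivity(g)
            elif name == "assortativity":
                out[name] = assortativity(g)
            elif name == "modularity_Q":
                out[name] = modularity(g)[0] if has_edges else float("nan")
            else:
                raise ValueError(f"unknown global metric {name!r}")
        except UndefinedMetricError:
            out[name] = float("nan")
    if any(n in which for n in ("C_norm", "L_norm", "S")):
        if has_edges:
            try:
                ens = random_ensemble(g, size=ensemble_size, seed=seed)
                c_norm, l_norm, s = normalized_metrics(g, ens)
            except UndefinedMetricError:
                c_norm = l_norm = s = float("nan")
        else:
            c_norm = l_norm = s = float("nan")
        for name, val in (("C_norm", c_norm), ("L_norm", l_norm), ("S", s)):
            if name in which:
                out[name] = val
    return out


def metrics_over_series(
    fc: FCSeries,
    spec: BinarizationSpec,
    which: Iterable[str] = DEFAULT_GLOBAL,
    nodal: Iterable[str] = (),
    ensemble_size: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metric trajectories over every (window, threshold) pair.

    Returns a wide global table (columns: window, threshold, metrics) and
    a long nodal table (window, threshold, node, metric, value); the
    nodal table is empty unless nodal metrics are requested.  The seed
    for each window/threshold's random ensemble is derived
    deterministically from ``seed`` so serial and parallel evaluation
    orders give identical results.
    """
    which = list(which)
    nodal = list(nodal)
    thresholds = spec.threshold_values()
    rows = []
    nodal_rows = []
    for w in range(fc.n_windows):
        mat = fc.matrices[w]
        for ti, thr in enumerate(thresholds):
            g = binarize(mat, spec, float(thr), node_labels=fc.roi_labels)
            row = {"window": w + 1, "threshold": float(thr)}
            row.update(
                global_metrics(
                    g,
                    ensemble_size=ensemble_size,
                    seed=seed + 7919 * w + ti,
                    which=which,
                )
            )
            rows.append(row)
            if nodal:
                nm = nodal_metrics(g)
                for metric in nodal:
                    vals = getattr(nm, metric)
                    for node, val in zip(nm.node_labels, vals):
                        nodal_rows.append(
                            {
                                "window": w + 1,
                                "threshold": float(thr),
                                "node": node,
                                "metric": metric,
                                "value": float(val),
                            }
                        )
    global_df = pd.DataFrame(rows)
    nodal_df = pd.DataFrame(
        nodal_rows, columns=["window", "threshold", "node", "metric", "value"]
    )
    return global_df, nodal_df
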