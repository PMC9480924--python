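"""Weighted graph-theory measures on nonnegative symmetric adjacency matrices.

All measures follow the weighted-network conventions of the brain-connectivity
literature.  Edge weights are connection strengths; shortest-path measures map
weight to length as L_ij = 1/w_ij (stronger connections are shorter), the
standard convention which the source measures never state explicitly.

Implemented here from first principles (no graph library):

* node strength — sum of edge weights;
* shortest paths — Dijkstra per source with shortest-path multiplicity
  counts, plus a vectorised min-plus (Floyd–Warshall) distance matrix used
  by the efficiency measures;
* betweenness centrality — Brandes' accumulation over ordered pairs with
  fractional counting across equal-length shortest paths, normalised by
  (N-1)(N-2);
* clustering coefficient — Onnela triangle intensity on weights scaled by
  the network maximum;
* global efficiency — mean inverse shortest-path length over ordered pairs
  (unreachable pairs contribute zero);
* local efficiency — global efficiency of each node's neighbour subgraph
  (Latora–Marchiori form; a toolbox-style cube-root weighted variant is
  available behind a flag);
* AUC of a metric over a sparsity grid — trapezoidal integral.
"""

from __future__ import annotations

from dataclasses import dataclass
from heapq import heappush, heappop

import numpy as np

__all__ = [
    "NodalMetrics",
    "MetricCurve",
    "node_strength",
    "to_length_matrix",
    "shortest_paths",
    "distance_matrix",
    "betweenness_centrality",
    "clustering_coefficient",
    "global_efficiency",
    "local_efficiency",
    "metric_auc",
    "nodal_metrics",
]

NODAL_METRIC_NAMES = ("bc", "strength", "cc", "eloc")


@dataclass
class NodalMetrics:
    """Per-node measures plus the scalar global efficiency of one network."""

    bc: np.ndarray
    strength: np.ndarray
    cc: np.ndarray
    eloc: np.ndarray
    eglob: float
    bc_raw: np.ndarray | None = None

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"bc": self.bc, "strength": self.strength, "cc": self.cc, "eloc": self.eloc}


@dataclass
class MetricCurve:
    """A metric evaluated on a strictly increasing sparsity grid, with AUC."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("sparsity grid must be strictly increasing")
        if self.values.shape[0] != self.grid.shape[0]:
            raise ValueError("values must align with the grid")

    @property
    def auc(self) -> float:
        return metric_auc(self)


def _check_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if (w < 0).any():
        raise ValueError("adjacency must be nonnegative")
    return w


def node_strength(weights: np.ndarray) -> np.ndarray:
    """Strength: sum of a node's edge weights (weighted degree)."""
    return _check_weights(weights).sum(axis=1)


def to_length_matrix(weights: np.ndarray) -> np.ndarray:
    """Map weights to lengths: L = 1/w for w > 0, +inf otherwise, zero diagonal."""
    w = _check_weights(weights)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def _adjacency_lists(lengths: np.ndarray):
    n = lengths.shape[0]
    nbrs, lens = [], []
    for i in range(n):
        finite = np.flatnonzero(np.isfinite(lengths[i]))
        finite = finite[finite != i]
        nbrs.append(finite)
        lens.append(lengths[i, finite])
    return nbrs, lens


def _dijkstra(source, nbrs, lens, n):
    """Single-source Dijkstra returning distances, path counts, predecessor
    lists and nodes in non-decreasing distance order (Brandes bookkeeping)."""
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    sigma[source] = 1.0
    preds: list[list[int]] = [[] for _ in range(n)]
    seen = {source: 0.0}
    order: list[int] = []
    done = np.zeros(n, dtype=bool)
    heap = [(0.0, source)]
    while heap:
        d, u = heappop(heap)
        if done[u]:
            continue
        done[u] = True
        dist[u] = d
        order.append(u)
        for v, luv in zip(nbrs[u], lens[u]):
            if done[v]:
                continue
            alt = d + luv
            if v not in seen or alt < seen[v]:
                seen[v] = alt
                heappush(heap, (alt, v))
                sigma[v] = sigma[u]
                preds[v] = [u]
            elif alt == seen[v]:
                sigma[v] += sigma[u]
                preds[v].append(u)
    return dist, sigma, preds, order


def shortest_paths(lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest distances and shortest-path multiplicities.

    Runs Dijkstra from every source on the length matrix.  Returns the
    distance matrix (inf for unreachable pairs) and the matrix of counts of
    distinct shortest paths per ordered pair (0 for unreachable, 1 on the
    diagonal).
    """
    lengths = np.asarray(lengths, dtype=float)
    n = lengths.shape[0]
    nbrs, lens = _adjacency_lists(lengths)
    dist = np.empty((n, n))
    counts = np.empty((n, n))
    for s in range(n):
        d, sigma, _, _ = _dijkstra(s, nbrs, lens, n)
        dist[s] = d
        counts[s] = sigma
    counts[~np.isfinite(dist)] = 0.0
    return dist, counts


def distance_matrix(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest distances by vectorised min-plus relaxation.

    Floyd–Warshall with numpy row broadcasting; O(N^3) but fast in practice
    for the ~100-node networks this package targets, and used internally by
    the efficiency measures.
    """
    d = np.array(lengths, dtype=float)
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    for k in range(n):
        np.minimum(d, d[:, k, None] + d[None, k, :], out=d)
    return d


def betweenness_centrality(
    weights: np.ndarray, normalized: bool = True
) -> np.ndarray:
    """Brandes betweenness on the 1/w length graph.

    Counts ordered source-target pairs with fractional credit across
    equal-length shortest paths; endpoints excluded.  Normalised by
    (N-1)(N-2) so values lie in [0, 1]; pass ``normalized=False`` for raw
    accumulations.
    """
    w = _check_weights(weights)
    n = w.shape[0]
    lengths = to_length_matrix(w)
    nbrs, lens = _adjacency_lists(lengths)
    bc = np.zeros(n)
    for s in range(n):
        _, sigma, preds, order = _dijkstra(s, nbrs, lens, n)
        delta = np.zeros(n)
        for u in reversed(order):
            for p in preds[u]:
                delta[p] += sigma[p] / sigma[u] * (1.0 + delta[u])
            if u != s:
                bc[u] += delta[u]
    if normalized and n > 2:
        bc = bc / ((n - 1) * (n - 2))
    return bc


def clustering_coefficient(weights: np.ndarray) -> np.ndarray:
    """Onnela triangle-intensity clustering on max-scaled weights.

    cc_i = sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) / (k_i (k_i - 1)) with
    w' = w / max(w); zero for nodes with fewer than two neighbours.
    """
    w = _check_weights(weights)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    cbrt = np.cbrt(w / wmax)
    tri = np.diagonal(cbrt @ cbrt @ cbrt).copy()  # 2x triangle intensity per node
    k = np.count_nonzero(w > 0, axis=1)
    denom = k * (k - 1)
    out = np.zeros(w.shape[0])
    ok = denom > 0
    out[ok] = tri[ok] / denom[ok]
    return out


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].mean())


def global_efficiency(weights: np.ndarray) -> float:
    """Mean of 1/d_ij over ordered node pairs (0 for unreachable pairs)."""
    w = _check_weights(weights)
    return _efficiency_from_distances(distance_matrix(to_length_matrix(w)))


def local_efficiency(weights: np.ndarray, variant: str = "subgraph") -> np.ndarray:
    """Local efficiency per node.

    variant="subgraph" (default): global efficiency of the subgraph induced
    on each node's neighbours with the node removed and paths confined to
    the subgraph — the literal "average inverse shortest path length between
    the direct neighbours of a node when it is removed".

    variant="toolbox": the cube-root weighted form used by the brain
    connectivity toolbox, eloc_i = sum_{j,h} (w_ij w_ih / d_jh(N_i))^(1/3)
    / (k_i (k_i - 1)), with d computed within the neighbour subgraph.

    Nodes with fewer than two neighbours score zero under both variants.
    """
    if variant not in ("subgraph", "toolbox"):
        raise ValueError(f"unknown local-efficiency variant {variant!r}")
    w = _check_weights(weights)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        if variant == "subgraph":
            out[i] = global_efficiency(sub)
        else:
            d = distance_matrix(to_length_matrix(sub))
            with np.errstate(divide="ignore"):
                invd = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
            wi = w[i, nbrs]
            terms = np.cbrt(np.outer(wi, wi) * invd)
            np.fill_diagonal(terms, 0.0)
            k = nbrs.size
            out[i] = terms.sum() / (k * (k - 1))
    return out


def metric_auc(curve: MetricCurve) -> float:
    """Trapezoidal area under a metric-versus-sparsity curve."""
    if curve.grid.size < 2:
        raise ValueError("AUC needs at least two grid points")
    return float(np.trapezoid(curve.values, curve.grid))


def nodal_metrics(weights: np.ndarray, eloc_variant: str = "subgraph") -> NodalMetrics:
    """All five measures of one thresholded network in a single call."""
    w = _check_weights(weights)
    bc_raw = betweenness_centrality(w, normalized=False)
    n = w.shape[0]
    bc = bc_raw / ((n - 1) * (n - 2)) if n > 2 else bc_raw.copy()
    return NodalMetrics(
        bc=bc,
        strength=node_strength(w),
        cc=clustering_coefficient(w),
        eloc=local_efficiency(w, variant=eloc_variant),
        eglob=global_efficiency(w),
        bc_raw=bc_raw,
    )
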