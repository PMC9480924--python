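"""Construction of positive weighted functional networks from ROI time series.

The pipeline stages implemented here follow the standard resting-state
functional connectivity workflow: per-subject Pearson correlation between
regional time series, edge-wise removal of age and sex effects across the
cohort with an ordinary general linear model, rectification of negative
correlations, and proportional (sparsity-based) thresholding that keeps the
strongest fraction of edges.  Sparsity is the number of retained edges
divided by the number of possible edges N(N-1)/2.  The group-level sparsity
is selected as the smallest sparsity at which every subject's network is a
single connected component (cost minimised while all nodes are connected).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ROITimeSeries",
    "ConnectivityMatrix",
    "ThresholdedNetwork",
    "pearson_connectivity",
    "residualize_edges",
    "rectify_negative",
    "network_sparsity",
    "threshold_to_sparsity",
    "largest_component_size",
    "min_connecting_sparsity",
    "select_group_sparsity",
    "UNREACHABLE",
]

#: Sentinel returned by :func:`min_connecting_sparsity` when no sparsity can
#: connect all nodes (some node has no positive edge at all).
UNREACHABLE = math.inf


@dataclass
class ROITimeSeries:
    """One subject's T x N matrix of ROI-averaged signals."""

    subject_id: str
    data: np.ndarray  # shape (t_points, n_nodes)
    node_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (timepoints x nodes)")
        if self.data.shape[1] != len(self.node_names):
            raise ValueError(
                f"subject {self.subject_id}: {self.data.shape[1]} columns but "
                f"{len(self.node_names)} node names"
            )
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject_id}: non-finite values in time series")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def t_points(self) -> int:
        return self.data.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric zero-diagonal edge-weight matrix with a processing-stage flag."""

    weights: np.ndarray
    stage: str  # {"raw", "residualized", "rectified"}
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) > 1e-12:
            raise ValueError("connectivity matrix must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class ThresholdedNetwork:
    """Weighted adjacency at a given sparsity, with component bookkeeping."""

    weights: np.ndarray
    sparsity: float
    lcc_size: int
    target_sparsity: float = field(default=np.nan)
    subject_id: str = ""

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _n_pairs(n: int) -> int:
    return n * (n - 1) // 2


def pearson_connectivity(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of ROI time series.

    The raw correlation coefficients are stored as edge weights (no Fisher
    r-to-z transform); the diagonal is set to zero.
    """
    if ts.t_points < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.node_names[i] for i in dead)
        raise ValueError(f"subject {ts.subject_id}: constant time series at node(s) {names}")
    w = np.corrcoef(ts.data, rowvar=False)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0  # enforce exact symmetry against float noise
    return ConnectivityMatrix(w, stage="raw", subject_id=ts.subject_id)


def _sex_to_numeric(sex: np.ndarray) -> np.ndarray:
    out = np.asarray([1.0 if str(s).upper().startswith("M") else 0.0 for s in sex])
    return out


def residualize_edges(matrices, subjects) -> list[ConnectivityMatrix]:
    """Remove linear age and sex effects from every edge across subjects.

    For each edge (i, j) an OLS model ``value ~ 1 + age + sex`` is fitted
    across all subjects (groups pooled); the edge value is replaced by its
    residual plus the model prediction at the covariate mean, so the grand
    mean of every edge is preserved.  A collinear covariate (e.g. a
    single-sex cohort) is dropped with a warning.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to residualize")
    n_sub = len(matrices)
    if len(subjects) != n_sub:
        raise ValueError("one subject row per matrix required")
    n = matrices[0].n_nodes
    iu = np.triu_indices(n, k=1)
    edges = np.stack([m.weights[iu] for m in matrices])  # (n_sub, n_edges)

    age = np.asarray(subjects["age"], dtype=float)
    sex = _sex_to_numeric(np.asarray(subjects["sex"]))
    cols = [np.ones(n_sub)]
    for name, col in (("age", age), ("sex", sex)):
        if np.ptp(col) == 0:
            warnings.warn(f"covariate '{name}' is constant across subjects; dropped")
        else:
            cols.append(col)
    x = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(x, edges, rcond=None)
    fitted = x @ beta
    at_mean = x.mean(axis=0) @ beta  # prediction at covariate mean == grand mean
    resid = edges - fitted + at_mean

    out = []
    for k, m in enumerate(matrices):
        w = np.zeros((n, n))
        w[iu] = resid[k]
        w = w + w.T
        out.append(ConnectivityMatrix(w, stage="residualized", subject_id=m.subject_id))
    return out


def rectify_negative(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Set negative edge weights to zero (positive correlation matrix)."""
    w = np.maximum(matrix.weights, 0.0)
    return ConnectivityMatrix(w, stage="rectified", subject_id=matrix.subject_id)


def network_sparsity(weights: np.ndarray) -> float:
    """Fraction of possible edges present (weight > 0)."""
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(np.count_nonzero(weights[iu] > 0) / _n_pairs(n))


def _sorted_positive_edges(weights: np.ndarray):
    """Positive upper-triangle edges sorted by weight desc, ties by (i, j)."""
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    pos = w > 0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def _build_from_edges(n: int, ei, ej, ew) -> np.ndarray:
    w = np.zeros((n, n))
    w[ei, ej] = ew
    w[ej, ei] = ew
    return w


def largest_component_size(weights: np.ndarray) -> int:
    """Size of the largest connected component (an edge is any weight > 0).

    A graph with no edges has largest component size 1 (an isolated node),
    by convention.
    """
    adj = csr_matrix(np.asarray(weights) > 0)
    n_comp, labels = connected_components(adj, directed=False)
    return int(np.bincount(labels).max())


def threshold_to_sparsity(
    matrix: ConnectivityMatrix, target_s: float
) -> ThresholdedNetwork:
    """Keep the k strongest edges, k = round(target_s * N(N-1)/2).

    Weights of surviving edges are retained (no binarisation).  Ties at the
    cutoff weight are broken deterministically by lexicographic (i, j) edge
    order.  If fewer than k positive edges exist, all positive edges are
    kept and a warning reports the shortfall.
    """
    if not 0 < target_s <= 1:
        raise ValueError("target sparsity must be in (0, 1]")
    n = matrix.n_nodes
    m = _n_pairs(n)
    k = int(math.floor(target_s * m + 0.5))  # round half up, documented tie rule
    ei, ej, ew = _sorted_positive_edges(matrix.weights)
    if k > ew.size:
        warnings.warn(
            f"subject {matrix.subject_id}: only {ew.size} positive edges; "
            f"target sparsity {target_s:.3f} needs {k}"
        )
        k = ew.size
    w = _build_from_edges(n, ei[:k], ej[:k], ew[:k])
    return ThresholdedNetwork(
        weights=w,
        sparsity=k / m,
        lcc_size=largest_component_size(w),
        target_sparsity=target_s,
        subject_id=matrix.subject_id,
    )


def min_connecting_sparsity(matrix: ConnectivityMatrix) -> float:
    """Smallest sparsity at which all nodes form one connected component.

    Searches at single-edge resolution: binary search over the retained edge
    count k (the largest-component size is nondecreasing in k).  Returns
    :data:`UNREACHABLE` (inf) with a warning naming an isolated node if even
    the full positive matrix is disconnected.
    """
    n = matrix.n_nodes
    m = _n_pairs(n)
    ei, ej, ew = _sorted_positive_edges(matrix.weights)

    def lcc_at(k: int) -> int:
        return largest_component_size(_build_from_edges(n, ei[:k], ej[:k], ew[:k]))

    if ew.size == 0 or lcc_at(ew.size) < n:
        degree = np.count_nonzero(matrix.weights > 0, axis=0)
        lonely = int(np.argmin(degree))
        warnings.warn(
            f"subject {matrix.subject_id}: network cannot be fully connected "
            f"(e.g. node index {lonely} has degree {degree[lonely]})"
        )
        return UNREACHABLE

    lo, hi = n - 1, ew.size  # a spanning structure needs at least N-1 edges
    if lcc_at(lo) == n:
        return lo / m
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if lcc_at(mid) == n:
            hi = mid
        else:
            lo = mid
    return hi / m


def select_group_sparsity(matrices) -> tuple[float, float]:
    """Group-level sparsity selection over a cohort of rectified matrices.

    Returns ``(selected_s, min_s)``: the sparsity at which ALL subjects are
    fully connected (max over per-subject minima) and the sparsity at which
    at least ONE subject is fully connected (min over per-subject minima).
    Both are reported at 0.1% resolution.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one subject")
    minima = [min_connecting_sparsity(m) for m in matrices]
    bad = [m.subject_id for m, s in zip(matrices, minima) if not math.isfinite(s)]
    if bad:
        raise ValueError(f"subjects with unconnectable networks: {', '.join(bad)}")
    selected = max(minima)
    lowest = min(minima)
    return round(selected * 1000) / 1000, round(lowest * 1000) / 1000
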