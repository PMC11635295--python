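"""Graph-theory characterisation of thresholded FC networks.

A subject's FC matrix is binarised over a sparsity grid (default 0.05 to
0.80, step 0.05): at sparsity s the k = round(s * N(N-1)/2) largest raw
correlations become edges (undirected, unweighted).  Four global metrics are
computed at every grid point and summarised by the trapezoidal area under
the curve (AUC):

* Lp   characteristic path length:  mean of d_ij over ordered node pairs
       (i != j).  Disconnected pairs (d = inf) are excluded from the mean
       ("connected-pairs" convention) and their count is reported.
* Cp   clustering coefficient: node-mean of E_i / (D_i (D_i - 1)/2), where
       D_i is node i's degree and E_i the edge count among its neighbours;
       the node term is 0 when D_i < 2.
* Eg   global efficiency: mean of 1/d_ij over ordered pairs, 1/inf = 0.
* Eloc local efficiency: node-mean of the global efficiency of the subgraph
       induced by each node's neighbours (0 for < 2 neighbours).

Deterministic conventions: edge count rounding is round-half-up; rank ties
at the cutoff are broken lexicographically by (i, j).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

from .connectivity import FCMatrix

__all__ = [
    "default_sparsity_grid",
    "BinaryNetwork",
    "NetworkMetrics",
    "threshold_by_sparsity",
    "shortest_paths",
    "char_path_length",
    "clustering_coeff",
    "global_efficiency",
    "local_efficiency",
    "metric_auc",
    "metrics_over_grid",
]

METRIC_NAMES = ("Lp", "Cp", "Eg", "Eloc")


def default_sparsity_grid() -> np.ndarray:
    """Sparsity values 0.05, 0.10, ..., 0.80 (16 points)."""
    return np.round(np.arange(1, 17) * 0.05, 10)


@dataclass
class BinaryNetwork:
    """Undirected, unweighted network over the active FC nodes."""

    adjacency: np.ndarray  # (N, N) bool, symmetric, zero diagonal
    node_ids: np.ndarray  # 1-based channel ids of the N nodes
    sparsity: float  # requested sparsity s

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(a != a.T) or np.any(np.diagonal(a)):
            raise ValueError("adjacency must be symmetric with zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def achieved_sparsity(self) -> float:
        m = self.n_nodes * (self.n_nodes - 1) // 2
        return self.n_edges / m if m else 0.0


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def threshold_by_sparsity(
    fc: FCMatrix, s: float, rank_by_absolute: bool = False
) -> BinaryNetwork:
    """Binarise an FC matrix at sparsity s by keeping the k largest raw r.

    k = round_half_up(s * N(N-1)/2) over the active nodes.  Ranking uses raw
    (signed) correlations by default — positive-coupling networks —
    ``rank_by_absolute`` switches to |r|.  Ties at the cutoff are resolved
    in lexicographic (i, j) order, so the edge set is stable across runs.
    A k of 0 returns an empty graph with a warning.
    """
    if not 0 < s <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {s}")
    idx = np.flatnonzero(fc.active)
    n = len(idx)
    if n < 2:
        raise ValueError("need >= 2 active nodes to build a network")
    sub = fc.r[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(n, k=1)
    vals = sub[iu, ju]
    if np.any(~np.isfinite(vals)):
        raise ValueError("FC matrix has missing values among active nodes")
    if rank_by_absolute:
        vals = np.abs(vals)
    m = len(vals)
    k = _round_half_up(s * m)
    adj = np.zeros((n, n), dtype=bool)
    if k == 0:
        warnings.warn(f"sparsity {s} yields 0 edges on {n} nodes", stacklevel=2)
    else:
        # sort by (-r, i, j): descending r, lexicographic tie-break
        order = np.lexsort((ju, iu, -vals))
        keep = order[:k]
        adj[iu[keep], ju[keep]] = True
        adj |= adj.T
    return BinaryNetwork(adjacency=adj, node_ids=idx + 1, sparsity=float(s))


def shortest_paths(net: BinaryNetwork) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths; inf for unreachable pairs."""
    n = net.n_nodes
    if n == 0:
        return np.zeros((0, 0))
    sparse = csr_matrix(net.adjacency.astype(np.int8))
    d = _csgraph_sp(sparse, method="D", unweighted=True, directed=False)
    return d


def char_path_length(
    net: BinaryNetwork, dist: np.ndarray | None = None
) -> tuple[float, int]:
    """Characteristic path length Lp and the number of excluded ordered pairs.

    Lp is the mean of d_ij over ordered pairs i != j; infinite distances are
    excluded from the average (connected-pairs convention).  Returns
    (nan, all pairs) for a graph with no finite off-diagonal distance.
    """
    if net.n_nodes < 2:
        raise ValueError("Lp needs >= 2 nodes")
    d = shortest_paths(net) if dist is None else dist
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    n_excluded = int(off.sum() - finite.sum())
    if not np.any(finite):
        return float("nan"), n_excluded
    return float(d[finite].mean()), n_excluded


def global_efficiency(net: BinaryNetwork, dist: np.ndarray | None = None) -> float:
    """Global efficiency Eg: mean of 1/d_ij over ordered pairs, 1/inf = 0."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("Eg needs >= 2 nodes")
    d = shortest_paths(net) if dist is None else dist
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def clustering_coeff(net: BinaryNetwork) -> float:
    """Clustering coefficient Cp: node-mean of E_i / (D_i(D_i-1)/2).

    E_i is the number of edges among node i's neighbours; the node term is
    defined as 0 for degree < 2.
    """
    if net.n_nodes < 1:
        raise ValueError("Cp needs >= 1 node")
    a = net.adjacency.astype(np.int64)
    deg = a.sum(axis=1)
    # edges among neighbours of i = (A^3)_ii / 2
    tri2 = np.diagonal(a @ a @ a)  # 2 * E_i * ... actually = 2*E_i
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = deg * (deg - 1)
        terms = np.where(deg >= 2, tri2 / np.maximum(denom, 1), 0.0)
    return float(terms.mean())


def _subgraph_eg(adj: np.ndarray) -> float:
    """Global efficiency of a small adjacency matrix (0 for < 2 nodes)."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = _csgraph_sp(csr_matrix(adj.astype(np.int8)), method="D",
                    unweighted=True, directed=False)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def local_efficiency(net: BinaryNetwork) -> float:
    """Local efficiency Eloc: node-mean of Eg of each neighbourhood subgraph."""
    if net.n_nodes < 1:
        raise ValueError("Eloc needs >= 1 node")
    a = net.adjacency
    terms = np.empty(net.n_nodes)
    for i in range(net.n_nodes):
        nb = np.flatnonzero(a[i])
        terms[i] = _subgraph_eg(a[np.ix_(nb, nb)]) if len(nb) >= 2 else 0.0
    return float(terms.mean())


def metric_auc(curve: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoidal AUC of a metric curve over the sparsity grid.

    Missing values are an error (the integral would be undefined); the
    offending sparsity points are named.
    """
    curve = np.asarray(curve, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if curve.shape != grid.shape or len(grid) < 2:
        raise ValueError("curve and grid must have equal length >= 2")
    bad = ~np.isfinite(curve)
    if np.any(bad):
        pts = ", ".join(f"{g:g}" for g in grid[bad])
        raise ValueError(f"metric curve has missing values at sparsity {pts}")
    return float(np.trapezoid(curve, grid))


@dataclass
class NetworkMetrics:
    """Metric curves over the sparsity grid and their AUC scalars."""

    grid: np.ndarray
    curves: dict[str, np.ndarray]
    auc: dict[str, float]
    n_nodes: int
    excluded_pairs: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    subject_id: str = "subject"

    def to_rows(self) -> list[dict]:
        rows = []
        for name, curve in self.curves.items():
            for s, v in zip(self.grid, curve):
                rows.append({"subject": self.subject_id, "metric": name,
                             "sparsity": float(s), "value": float(v)})
        return rows


def metrics_over_grid(
    fc: FCMatrix,
    grid: np.ndarray | None = None,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> NetworkMetrics:
    """Compute the requested metrics at every sparsity and their AUCs."""
    grid = default_sparsity_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or np.any((grid <= 0) | (grid > 1)):
        raise ValueError("sparsity grid must be strictly increasing within (0, 1]")
    unknown = set(metrics) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    curves = {m: np.empty(len(grid)) for m in metrics}
    excluded = np.zeros(len(grid), dtype=int)
    n_nodes = 0
    for gi, s in enumerate(grid):
        net = threshold_by_sparsity(fc, float(s))
        n_nodes = net.n_nodes
        dist = shortest_paths(net) if ("Lp" in metrics or "Eg" in metrics) else None
        if "Lp" in metrics:
            curves["Lp"][gi], excluded[gi] = char_path_length(net, dist)
        if "Eg" in metrics:
            curves["Eg"][gi] = global_efficiency(net, dist)
        if "Cp" in metrics:
            curves["Cp"][gi] = clustering_coeff(net)
        if "Eloc" in metrics:
            curves["Eloc"][gi] = local_efficiency(net)
    auc = {m: metric_auc(curves[m], grid) for m in metrics}
    return NetworkMetrics(grid=grid, curves=curves, auc=auc, n_nodes=n_nodes,
                          excluded_pairs=excluded, subject_id=fc.subject_id)
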