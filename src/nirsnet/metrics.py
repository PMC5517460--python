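"""Sparsity thresholding and graph metrics of thresholded FC networks.

Networks are built by ranking the n(n-1)/2 upper-triangle correlations in
descending order and keeping the strongest round(sparsity * M) edges, so every
subject's graph has the same edge count at a given sparsity.  Binary mode sets
kept edges to 1; weighted mode retains the surviving r-values as weights.

Metrics (binary and weighted):

* nodal efficiency      E_nodal(i) = 1/(N-1) * sum_j 1/d_ij
* global efficiency     E_glob = mean_i E_nodal(i)
* local efficiency      E_loc = 1/N * sum_i E_glob(G_i), G_i the subgraph
                        induced on i's neighbours
* clustering            C = 1/n * sum_i 2 t_i / (k_i (k_i - 1)); weighted mode
                        uses the geometric-mean (Onnela) triangle intensity
                        with max-weight normalization
* nodal betweenness     b_i = 1/((n-1)(n-2)) * sum over unordered pairs
                        {h, j} (h, j != i) of rho_hj(i) / rho_hj

Weighted shortest-path lengths use edge length 1/weight.  Unreachable pairs
contribute zero efficiency and are excluded from betweenness ratios.  The AUC
of a metric curve over the sparsity grid is its composite trapezoidal
integral, a threshold-independent summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import ConnectivityMatrix

__all__ = [
    "ThresholdedNetwork",
    "threshold_network",
    "edge_count",
    "shortest_paths",
    "nodal_efficiency",
    "nodal_betweenness",
    "clustering_coefficient",
    "global_efficiency",
    "local_efficiency",
    "metric_auc",
    "network_profile",
]


@dataclass
class ThresholdedNetwork:
    """Undirected graph at a given sparsity (0/1 or retained r-values)."""

    adjacency: np.ndarray
    sparsity: float
    mode: str  # "binary" | "weighted"

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.diag(A).any():
            raise ValueError("adjacency must have zero diagonal")
        if self.mode not in ("binary", "weighted"):
            raise ValueError("mode must be 'binary' or 'weighted'")
        if (A < 0).any():
            raise ValueError("edge weights must be positive")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    def lengths(self) -> np.ndarray:
        """Edge lengths for shortest paths: 1 (binary) or 1/weight (weighted)."""
        A = self.adjacency
        if self.mode == "binary":
            return (A > 0).astype(float)
        return np.where(A > 0, 1.0 / np.where(A > 0, A, 1.0), 0.0)


def edge_count(sparsity: float, n_nodes: int, rounding: str = "round") -> int:
    """round(sparsity * n(n-1)/2), half away from zero (or floor)."""
    m = sparsity * n_nodes * (n_nodes - 1) / 2.0
    if rounding == "round":
        return int(np.floor(m + 0.5))
    if rounding == "floor":
        return int(np.floor(m))
    raise ValueError("rounding must be 'round' or 'floor'")


def _ranked_edges(values: np.ndarray):
    """Upper-triangle edges sorted by descending r, ties by (i, j) lexicographic."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, 1)
    r = values[iu, ju]
    order = np.lexsort((ju, iu, -r))
    return iu[order], ju[order], r[order]


def threshold_network(
    fc: ConnectivityMatrix | np.ndarray,
    sparsity: float,
    mode: str = "binary",
    rounding: str = "round",
) -> ThresholdedNetwork:
    """Keep the top round(sparsity * M) positive correlations as edges.

    Negative correlations rank last and are never selected; if the requested
    edge count exceeds the number of positive entries the call fails with a
    count report.  Ties at the cutoff break deterministically by (i, j).
    """
    values = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, float)
    if not (0 < sparsity < 1):
        raise ValueError("sparsity must lie in (0, 1)")
    n = values.shape[0]
    k = edge_count(sparsity, n, rounding)
    iu, ju, r = _ranked_edges(values)
    n_positive = int(np.sum(r > 0))
    if k > n_positive:
        raise ValueError(
            f"sparsity {sparsity} requires {k} edges but only {n_positive} "
            f"positive correlations are available")
    A = np.zeros((n, n))
    sel = slice(0, k)
    w = np.ones(k) if mode == "binary" else r[sel]
    A[iu[sel], ju[sel]] = w
    A[ju[sel], iu[sel]] = w
    return ThresholdedNetwork(adjacency=A, sparsity=sparsity, mode=mode)


# ---------------------------------------------------------------------------
# distances and shortest-path counts
# ---------------------------------------------------------------------------


def _distance_matrix(lengths: np.ndarray, binary: bool) -> np.ndarray:
    graph = csr_matrix(lengths)
    return _csgraph_shortest_path(
        graph, method="D", directed=False, unweighted=binary)


def _dense_distances(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest distances of a small dense graph (vectorized
    Floyd-Warshall); `lengths` uses 0 for "no edge".  Cheaper than the sparse
    machinery for the neighbour subgraphs of local efficiency."""
    n = lengths.shape[0]
    D = np.where(lengths > 0, lengths, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        np.minimum(D, D[:, k, None] + D[None, k, :], out=D)
    return D


def _global_efficiency_from_lengths(lengths: np.ndarray) -> float:
    n = lengths.shape[0]
    D = _dense_distances(lengths)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def _path_counts(D: np.ndarray, lengths: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Number of shortest paths between every node pair.

    Computed as the fixpoint of sigma[h, j] = delta_hj + sum_k sigma[h, k] *
    P[h, k, j] over the predecessor relation P[h, k, j] = (edge k-j lies on a
    shortest h->j path); the relation is acyclic (distances strictly increase
    along it, all edge lengths being positive), so the iteration converges in
    at most diameter steps.  Vectorized over all sources at once.
    """
    n = D.shape[0]
    E = lengths > 0
    with np.errstate(invalid="ignore"):
        on_path = np.abs(D[:, :, None] + lengths[None, :, :] - D[:, None, :])
    tol = rtol * np.maximum(1.0, np.abs(D[:, None, :]))
    P = E[None, :, :] & (on_path <= tol) & np.isfinite(D)[:, :, None]
    eye = np.eye(n)
    for h in range(n):
        P[h, :, h] = False  # nothing flows back into the source
    sigma = eye.copy()
    for _ in range(n):
        new = eye + np.einsum("hk,hkj->hj", sigma, P)
        if np.array_equal(new, sigma):
            break
        sigma = new
    return sigma


def shortest_paths(net: ThresholdedNetwork):
    """All-pairs shortest-path distances and shortest-path counts.

    Binary graphs use hop counts (BFS); weighted graphs use Dijkstra with
    edge length 1/weight.  Unreachable pairs have distance +inf and count 0.
    """
    L = net.lengths()
    D = _distance_matrix(L, net.mode == "binary")
    sigma = _path_counts(D, L)
    return D, sigma


def _efficiency_from_distances(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_efficiency(net: ThresholdedNetwork, D: np.ndarray | None = None) -> np.ndarray:
    """E_nodal(i) = mean over j != i of 1/d_ij; unreachable pairs contribute 0."""
    if D is None:
        D = _distance_matrix(net.lengths(), net.mode == "binary")
    return _efficiency_from_distances(D)


def global_efficiency(net: ThresholdedNetwork, D: np.ndarray | None = None) -> float:
    """Mean of nodal efficiency across nodes (exactly, by definition)."""
    return float(np.mean(nodal_efficiency(net, D)))


def nodal_betweenness(
    net: ThresholdedNetwork,
    D: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
    rtol: float = 1e-9,
) -> np.ndarray:
    """Normalized shortest-path betweenness.

    b_i = 1/((n-1)(n-2)) * sum over *unordered* pairs {h, j}, h,j != i, of
    rho_hj(i)/rho_hj, with rho_hj(i) = rho_hi * rho_ij when i lies on a
    shortest h-j path.  Pairs with rho_hj = 0 (unreachable) contribute 0.
    """
    L = net.lengths()
    if D is None:
        D = _distance_matrix(L, net.mode == "binary")
    if sigma is None:
        sigma = _path_counts(D, L, rtol)
    n = D.shape[0]
    if n < 3:
        return np.zeros(n)
    valid = np.isfinite(D) & (sigma > 0)
    np.fill_diagonal(valid, False)
    b = np.zeros(n)
    for i in range(n):
        # i interior to a shortest h-j path  <=>  d_hi + d_ij == d_hj
        with np.errstate(invalid="ignore"):
            through = np.abs(D[:, i, None] + D[None, i, :] - D)
        tol = rtol * np.maximum(1.0, np.abs(D))
        mask = valid & (through <= tol)
        mask[i, :] = False
        mask[:, i] = False
        contrib = np.where(mask, np.outer(sigma[:, i], sigma[i, :]) / np.where(sigma > 0, sigma, 1.0), 0.0)
        b[i] = contrib.sum() / 2.0  # ordered -> unordered pairs
    return b / ((n - 1) * (n - 2))


def clustering_coefficient(net: ThresholdedNetwork):
    """Network clustering coefficient and its per-node values.

    Binary: C_i = 2 t_i / (k_i (k_i - 1)) with t_i the edges among i's
    neighbours.  Weighted: Onnela geometric-mean formulation on weights
    normalized by the maximum weight; degree from the binary skeleton.
    Nodes with fewer than 2 neighbours have C_i = 0.
    """
    A = (net.adjacency > 0).astype(float)
    k = A.sum(axis=1)
    denom = k * (k - 1)
    if net.mode == "binary":
        t2 = np.diag(A @ A @ A)          # 2 * t_i
    else:
        W = net.adjacency
        wmax = W.max()
        What = (W / wmax) ** (1.0 / 3.0) if wmax > 0 else W
        t2 = np.diag(What @ What @ What)
    with np.errstate(divide="ignore", invalid="ignore"):
        Ci = np.where(denom > 0, t2 / denom, 0.0)
    return float(np.mean(Ci)), Ci


def local_efficiency(net: ThresholdedNetwork) -> float:
    """E_loc = mean over nodes of the global efficiency of the subgraph
    induced on each node's neighbours (nodes with < 2 neighbours contribute 0)."""
    A = net.adjacency
    L = net.lengths()
    n = net.n_nodes
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(A[i] > 0)
        if nbrs.size < 2:
            continue
        total += _global_efficiency_from_lengths(L[np.ix_(nbrs, nbrs)])
    return total / n


def metric_auc(values: np.ndarray, grid: np.ndarray) -> float | np.ndarray:
    """Composite trapezoidal integral of a metric curve over the sparsity grid.

    `values` may be 1-D (global metric) or 2-D (nodes x sparsity), integrated
    along the last axis.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    if values.shape[-1] != grid.size:
        raise ValueError("curve/grid length mismatch")
    out = np.trapezoid(values, grid, axis=-1)
    return float(out) if out.ndim == 0 else out


def network_profile(
    fc: ConnectivityMatrix,
    grid: np.ndarray,
    mode: str = "binary",
    rounding: str = "round",
) -> dict:
    """All five metrics across the sparsity grid, plus their AUC summaries.

    Returns a dict with per-sparsity curves (``nodal_efficiency`` and
    ``nodal_betweenness`` are nodes x sparsity; the three global metrics are
    1-D) and matching ``*_auc`` entries.
    """
    n = fc.n_channels
    n_s = len(grid)
    ne = np.zeros((n, n_s))
    nb = np.zeros((n, n_s))
    cc = np.zeros(n_s)
    ge = np.zeros(n_s)
    le = np.zeros(n_s)
    for s_idx, s in enumerate(grid):
        net = threshold_network(fc, float(s), mode=mode, rounding=rounding)
        D, sigma = shortest_paths(net)
        ne[:, s_idx] = _efficiency_from_distances(D)
        nb[:, s_idx] = nodal_betweenness(net, D, sigma)
        cc[s_idx] = clustering_coefficient(net)[0]
        ge[s_idx] = float(np.mean(ne[:, s_idx]))
        le[s_idx] = local_efficiency(net)
    return {
        "grid": np.asarray(grid, dtype=float),
        "nodal_efficiency": ne,
        "nodal_betweenness": nb,
        "clustering_coefficient": cc,
        "global_efficiency": ge,
        "local_efficiency": le,
        "nodal_efficiency_auc": metric_auc(ne, grid),
        "nodal_betweenness_auc": metric_auc(nb, grid),
        "clustering_coefficient_auc": metric_auc(cc, grid),
        "global_efficiency_auc": metric_auc(ge, grid),
        "local_efficiency_auc": metric_auc(le, grid),
    }
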