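"""Weighted graph-theoretic network measures on thresholded FC matrices.

The two sessions' functional-connectivity matrices are turned into weighted
adjacency matrices by taking absolute values, zeroing the diagonal and
applying a single threshold — the 40th percentile of the pooled off-diagonal
values from BOTH sessions — so that the two conditions are compared on the
same edge-density footing.

Node measures: degree (count of nonzero edges), strength (sum of weights),
weighted clustering coefficient (Onnela: geometric mean of triangle weights,
weights normalized by the maximum), and local efficiency (global efficiency
of the neighbourhood subgraph).  Graph measures: characteristic path length
and global efficiency on 1/w distances, Louvain modularity (best of 10
seeded runs), and small-worldness against degree-preserving rewired nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .bha import FcMatrix


@dataclass
class AdjacencyMatrix:
    """Thresholded nonnegative weighted adjacency (symmetric, zero diagonal)."""

    weights: np.ndarray
    channel_names: list[str]
    threshold: float
    condition: str = "ASM-ON"
    patient_id: str = "P0"

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, float)
        if not np.allclose(W, W.T, atol=1e-12, equal_nan=True):
            raise ValueError("adjacency must be symmetric")
        if np.nanmin(W) < 0:
            raise ValueError("adjacency weights must be nonnegative")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class GraphMetricsResult:
    """Per-node and whole-graph measures for one adjacency matrix."""

    degree: np.ndarray
    strength: np.ndarray
    clustering: np.ndarray
    local_efficiency: np.ndarray
    path_length: float
    modularity: float
    global_efficiency: float
    small_worldness: float
    connected: bool
    channel_names: list[str] = field(default_factory=list)


def build_adjacency(fc_on: FcMatrix, fc_off: FcMatrix) -> tuple[AdjacencyMatrix, AdjacencyMatrix]:
    """Threshold |FC| of both sessions at the 40th percentile of their pooled values.

    Off-diagonal upper-triangle absolute correlations from both matrices are
    pooled; the threshold is the 40th percentile (linear interpolation) of
    that pool and the SAME threshold is applied to both sessions.  Entries
    below the threshold become exactly 0; entries at or above it keep their
    weight.  Diagonals are zero.
    """
    if fc_on.channel_names != fc_off.channel_names:
        raise ValueError("FC matrices have different channel sets")
    iu = np.triu_indices(len(fc_on.channel_names), k=1)
    mats = []
    for fc in (fc_on, fc_off):
        A = np.abs(np.asarray(fc.values, float)).copy()
        np.fill_diagonal(A, 0.0)
        mats.append(A)
    pooled = np.concatenate([mats[0][iu], mats[1][iu]])
    pooled = pooled[~np.isnan(pooled)]
    thr = float(np.percentile(pooled, 40))
    out = []
    for A, fc in zip(mats, (fc_on, fc_off)):
        W = np.where(np.nan_to_num(A) >= thr, np.nan_to_num(A), 0.0)
        np.fill_diagonal(W, 0.0)
        out.append(
            AdjacencyMatrix(
                weights=W,
                channel_names=list(fc.channel_names),
                threshold=thr,
                condition=fc.condition,
                patient_id=fc.patient_id,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Node-level measures
# ---------------------------------------------------------------------------

def onnela_clustering(W: np.ndarray) -> np.ndarray:
    """Weighted clustering coefficient (Onnela variant) per node.

    Weights are normalized by the maximum weight; C_i is the sum of cube
    roots of triangle weight products around i, divided by k_i(k_i−1).
    Nodes with degree < 2 have C_i = 0.
    """
    W = np.asarray(W, float)
    if W.max() <= 0:
        return np.zeros(W.shape[0])
    Wn = W / W.max()
    cr = np.cbrt(Wn)
    triangles = np.diag(cr @ cr @ cr)  # 2x number of weighted triangles around i
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, triangles / denom, 0.0)
    return C


def _distance_matrix(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight."""
    with np.errstate(divide="ignore"):
        D = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(D, 0.0)
    return shortest_path(D, method="D", directed=False)


def _global_efficiency(W: np.ndarray) -> float:
    """Mean inverse shortest-path length over all ordered node pairs."""
    n = W.shape[0]
    if n < 2:
        return 0.0
    D = _distance_matrix(W)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D[off]) & (D[off] > 0), 1.0 / D[off], 0.0)
    return float(inv.mean())


def local_efficiency(W: np.ndarray) -> np.ndarray:
    """Per-node local efficiency: global efficiency of the neighbourhood subgraph.

    Weights are max-normalized first so that 1/w distances are ≥ 1 and the
    measure lands in [0, 1].  Nodes with fewer than two neighbours score 0.
    """
    W = np.asarray(W, float)
    n = W.shape[0]
    out = np.zeros(n)
    if W.max() <= 0:
        return out
    Wn = W / W.max()
    for i in range(n):
        nbrs = np.flatnonzero(Wn[i] > 0)
        if nbrs.size < 2:
            continue
        out[i] = _global_efficiency(Wn[np.ix_(nbrs, nbrs)])
    return out


def node_metrics(adj: AdjacencyMatrix) -> dict[str, np.ndarray]:
    """Degree, strength, Onnela clustering and local efficiency per node."""
    W = adj.weights
    n = adj.n_nodes
    degree = (W > 0).sum(axis=1).astype(int)
    strength = W.sum(axis=1)
    if n < 3:
        clustering = np.zeros(n)
        loc_eff = np.zeros(n)
    else:
        clustering = onnela_clustering(W)
        loc_eff = local_efficiency(W)
    return {
        "degree": degree,
        "strength": strength,
        "clustering": clustering,
        "local_efficiency": loc_eff,
    }


# ---------------------------------------------------------------------------
# Graph-level measures
# ---------------------------------------------------------------------------

def characteristic_path_length(W: np.ndarray) -> tuple[float, bool]:
    """Mean shortest-path distance over connected ordered pairs.

    Returns ``(L, connected)``; disconnected pairs are excluded from the
    average and flagged via ``connected=False``.
    """
    n = W.shape[0]
    if n < 2:
        return 0.0, True
    D = _distance_matrix(W)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D[off])
    if not finite.any():
        return float("inf"), False
    return float(D[off][finite].mean()), bool(finite.all())


def modularity_louvain(
    W: np.ndarray, seed: int = 0, n_runs: int = 10, resolution: float = 1.0
) -> float:
    """Best-of-``n_runs`` seeded Louvain modularity of the weighted graph."""
    G = nx.from_numpy_array(W)
    if G.number_of_edges() == 0:
        return 0.0
    best = -np.inf
    for k in range(n_runs):
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=resolution, seed=seed + k
        )
        q = nx.community.modularity(G, comms, weight="weight", resolution=resolution)
        best = max(best, q)
    return float(best)


def _rewired_null(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving (Maslov–Sneppen) rewiring with weight reshuffle."""
    G = nx.from_numpy_array((W > 0).astype(int))
    n_edges = G.number_of_edges()
    n = W.shape[0]
    if n_edges >= 2 and n_edges < n * (n - 1) // 2:  # complete graphs cannot be rewired
        try:
            nx.double_edge_swap(
                G, nswap=10 * n_edges, max_tries=1000 * n_edges + 100,
                seed=int(rng.integers(2**31)),
            )
        except nx.NetworkXAlgorithmError:
            pass  # dense graph: keep however many swaps succeeded in place
        except nx.NetworkXError:
            pass
    weights = W[np.triu_indices_from(W, k=1)]
    weights = rng.permutation(weights[weights > 0])
    Wn = np.zeros_like(W)
    for w, (u, v) in zip(weights, G.edges()):
        Wn[u, v] = Wn[v, u] = w
    return Wn


def small_worldness(
    W: np.ndarray, seed: int = 0, n_null: int = 20
) -> float:
    """σ = (C/C_rand) / (L/L_rand) against degree-preserving rewired nulls.

    ``C`` is the mean Onnela clustering, ``L`` the characteristic path
    length; the null values are averaged over ``n_null`` rewired networks
    (10·|E| swap attempts each, weights reshuffled onto the rewired edges).
    σ ≈ 1 for random graphs, σ > 1 for small-world organization.
    """
    if n_null < 1:
        return float("nan")
    rng = np.random.default_rng(seed)
    C = onnela_clustering(W).mean()
    L, _ = characteristic_path_length(W)
    c_null, l_null = [], []
    for _ in range(n_null):
        Wn = _rewired_null(W, rng)
        c_null.append(onnela_clustering(Wn).mean())
        l_null.append(characteristic_path_length(Wn)[0])
    C_rand = float(np.mean(c_null))
    L_rand = float(np.mean(l_null))
    if C_rand <= 0 or L_rand <= 0 or not np.isfinite(L) or not np.isfinite(L_rand):
        return float("nan")
    return float((C / C_rand) / (L / L_rand))


def global_metrics(adj: AdjacencyMatrix, seed: int = 0, n_null: int = 20) -> dict[str, float]:
    """Characteristic path length, modularity, global efficiency, small-worldness."""
    W = adj.weights
    if adj.n_nodes == 0 or (W > 0).sum() == 0:
        return {
            "path_length": 0.0, "modularity": 0.0, "global_efficiency": 0.0,
            "small_worldness": float("nan"), "connected": False,
        }
    L, connected = characteristic_path_length(W)
    return {
        "path_length": L,
        "modularity": modularity_louvain(W, seed=seed),
        "global_efficiency": _global_efficiency(W),
        "small_worldness": small_worldness(W, seed=seed, n_null=n_null),
        "connected": connected,
    }


def compute_graph_metrics(adj: AdjacencyMatrix, seed: int = 0, n_null: int = 20) -> GraphMetricsResult:
    """All node-level and graph-level measures for one adjacency matrix."""
    nm = node_metrics(adj)
    gm = global_metrics(adj, seed=seed, n_null=n_null)
    return GraphMetricsResult(
        degree=nm["degree"],
        strength=nm["strength"],
        clustering=nm["clustering"],
        local_efficiency=nm["local_efficiency"],
        path_length=gm["path_length"],
        modularity=gm["modularity"],
        global_efficiency=gm["global_efficiency"],
        small_worldness=gm["small_worldness"],
        connected=gm["connected"],
        channel_names=list(adj.channel_names),
    )
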