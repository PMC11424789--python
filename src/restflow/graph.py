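"""Proportional thresholding of connectivity matrices and nodal graph metrics.

Band-averaged PDC matrices are symmetrized (max of the two directions),
binarized at a fixed edge density, and summarized per node by six measures:
degree, cost, clustering coefficient, local efficiency, betweenness
centrality and average path length. All metrics are implemented directly
(BFS / Brandes) so they can be verified against both exhaustive brute force
and an independent graph library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pdc import BAND_ORDER, FlowMeasures

__all__ = [
    "ThresholdedGraph",
    "threshold_network",
    "NodeMetrics",
    "node_metrics",
    "PatientFeatures",
    "extract_soz_features",
    "METRIC_NAMES",
    "MEASURE_NAMES",
]

METRIC_NAMES = (
    "degree",
    "cost",
    "clustering",
    "local_efficiency",
    "betweenness",
    "avg_path_length",
)
#: the eight per-region measures compared between groups
MEASURE_NAMES = ("inflow", "outflow") + METRIC_NAMES


@dataclass
class ThresholdedGraph:
    adjacency: np.ndarray  # (n, n) binary, symmetric, zero diagonal
    density: float
    edge_weights: np.ndarray  # symmetrized weights pre-threshold (provenance)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def threshold_network(conn: np.ndarray, density: float = 0.15) -> ThresholdedGraph:
    """Binarize a (possibly directed) connectivity matrix at fixed edge density.

    The matrix is symmetrized by ``w_ij = max(conn[i,j], conn[j,i])`` and the
    strongest ``round(density * n(n-1)/2)`` undirected edges are kept. Ties
    are broken deterministically by (weight desc, i asc, j asc).
    """
    conn = np.asarray(conn, dtype=float)
    if conn.ndim != 2 or conn.shape[0] != conn.shape[1]:
        raise ValueError("conn must be square")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    n = conn.shape[0]
    w = np.maximum(conn, conn.T)
    np.fill_diagonal(w, 0.0)
    n_possible = n * (n - 1) // 2
    n_keep = int(round(density * n_possible))
    if n_keep < 1:
        raise ValueError(
            f"density {density} keeps zero of {n_possible} possible edges"
        )
    iu, ju = np.triu_indices(n, k=1)
    order = sorted(range(len(iu)), key=lambda k: (-w[iu[k], ju[k]], iu[k], ju[k]))
    adj = np.zeros((n, n), dtype=int)
    for k in order[:n_keep]:
        adj[iu[k], ju[k]] = adj[ju[k], iu[k]] = 1
    return ThresholdedGraph(adjacency=adj, density=density, edge_weights=w)


@dataclass
class NodeMetrics:
    """Per-node arrays of the six graph measures (length n each)."""

    degree: np.ndarray
    cost: np.ndarray
    clustering: np.ndarray
    local_efficiency: np.ndarray
    betweenness: np.ndarray
    avg_path_length: np.ndarray
    reachability: np.ndarray  # fraction of other nodes reachable from each node

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _bfs_dist(adj: np.ndarray, src: int) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full(n, -1, dtype=int)
    dist[src] = 0
    frontier = [src]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in np.flatnonzero(adj[u]):
                if dist[v] < 0:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def _brandes_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unweighted betweenness, normalized by (n-1)(n-2)/2 (undirected)."""
    n = adj.shape[0]
    bc = np.zeros(n)
    neighbors = [np.flatnonzero(adj[u]) for u in range(n)]
    for s in range(n):
        stack: list[int] = []
        pred: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = [s]
        qi = 0
        while qi < len(queue):
            v = queue[qi]
            qi += 1
            stack.append(v)
            for w in neighbors[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = np.zeros(n)
        for w in reversed(stack):
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # each unordered (s, t) pair counted twice
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm if norm > 0 else bc


def node_metrics(graph: ThresholdedGraph | np.ndarray) -> NodeMetrics:
    """Six nodal measures of a simple undirected graph.

    Conventions for degenerate cases: clustering and local efficiency are 0
    for nodes with fewer than 2 neighbors; average path length is taken over
    reachable nodes only (0 for isolated nodes) with the reachable fraction
    reported separately, so outputs never contain infinities.
    """
    adj = graph.adjacency if isinstance(graph, ThresholdedGraph) else np.asarray(graph)
    adj = (adj != 0).astype(int)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T) or np.any(np.diag(adj)):
        raise ValueError("adjacency must be symmetric with zero diagonal")
    n = adj.shape[0]
    degree = adj.sum(axis=1)
    cost = degree / (n - 1) if n > 1 else np.zeros(n)
    clustering = np.zeros(n)
    local_eff = np.zeros(n)
    apl = np.zeros(n)
    reach = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        k = len(nb)
        if k >= 2:
            sub = adj[np.ix_(nb, nb)]
            e = sub.sum() / 2
            clustering[i] = e / (k * (k - 1) / 2)
            # Latora-Marchiori: mean inverse distance within the neighbor subgraph
            inv_sum = 0.0
            for a in range(k):
                d = _bfs_dist(sub, a)
                for b_ in range(k):
                    if b_ != a and d[b_] > 0:
                        inv_sum += 1.0 / d[b_]
            local_eff[i] = inv_sum / (k * (k - 1))
        d = _bfs_dist(adj, i)
        reachable = d > 0
        reach[i] = reachable.sum() / (n - 1) if n > 1 else 0.0
        apl[i] = d[reachable].mean() if reachable.any() else 0.0
    betweenness = _brandes_betweenness(adj) if n > 2 else np.zeros(n)
    return NodeMetrics(
        degree=degree.astype(int),
        cost=cost,
        clustering=clustering,
        local_efficiency=local_eff,
        betweenness=betweenness,
        avg_path_length=apl,
        reachability=reach,
    )


@dataclass
class PatientFeatures:
    """The 8-measure x 4-band feature vector at a patient's SOZ region."""

    patient_id: str
    group: str
    soz_region: int
    values: dict[str, dict[str, float]]  # band -> measure -> value

    def flat(self) -> dict[str, float]:
        return {
            f"{measure}_{band}": self.values[band][measure]
            for band in self.values
            for measure in self.values[band]
        }


def extract_soz_features(
    flows: FlowMeasures,
    metrics_per_band: dict[str, NodeMetrics],
    soz_region: int,
    patient_id: str,
    group: str,
) -> PatientFeatures:
    """Assemble inflow/outflow plus the six graph metrics at the SOZ region."""
    missing = [b for b in BAND_ORDER if b not in metrics_per_band]
    if missing:
        raise ValueError(f"missing band metrics: {missing}")
    if flows.bands != tuple(BAND_ORDER):
        raise ValueError("flow measures must cover the four standard bands in order")
    n = flows.inflow.shape[0]
    if not (0 <= soz_region < n):
        raise ValueError(f"soz_region {soz_region} out of range [0, {n})")
    values: dict[str, dict[str, float]] = {}
    for k, band in enumerate(BAND_ORDER):
        m = metrics_per_band[band]
        values[band] = {
            "inflow": float(flows.inflow[soz_region, k]),
            "outflow": float(flows.outflow[soz_region, k]),
            **{name: float(arr[soz_region]) for name, arr in m.as_dict().items()},
        }
    return PatientFeatures(
        patient_id=patient_id, group=group, soz_region=int(soz_region), values=values
    )
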