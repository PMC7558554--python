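"""Interaction topologies: scale-free, small-world, random and complete graphs.

Graph generation is delegated to networkx; this module wraps the generated
graph together with symmetric tie strengths S_ij in (0, 1] and provides the
topology metrics used to characterize each family (mean shortest-path length,
global average of local clustering coefficients, mean degree). Metrics are
computed with scipy so that the complete graph on 1000 nodes remains a
seconds-scale computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from .population import TraitSpec

__all__ = [
    "SocialNetwork",
    "TopologyMetrics",
    "DEFAULT_TIE_SPEC",
    "generate_network",
    "assign_tie_strengths",
    "topology_metrics",
]

#: Tie strengths default to the same clipped-normal family as agent traits,
#: truncated to (0, 1] (no distribution is prescribed for them by the model).
DEFAULT_TIE_SPEC = TraitSpec(0.5, 0.15, 0.0, 1.0)

_MAX_RETRIES = 100
_EPS = 1e-6

#: networkx generator per topology family, with the default parameters used
#: for the 1000-node comparison (BA m=10 -> mean degree ~19.3; ER p=0.0202 ->
#: mean degree ~20.2; WS K=30, p=0.1 -> mean degree exactly 30).
DEFAULT_PARAMS = {
    "ba": {"m": 10},
    "ws": {"k": 30, "p": 0.1},
    "er": {"p": 0.0202},
    "complete": {},
}


@dataclass(frozen=True)
class TopologyMetrics:
    avg_path_length: float
    clustering_coefficient: float
    avg_degree: float


class SocialNetwork:
    """Undirected weighted interaction graph.

    Nodes are integers 0..n-1; every edge carries a strictly positive tie
    strength ``S_ij = S_ji``. The sparse strength matrix and the 0/1
    adjacency are cached for the vectorized interaction step.
    """

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() < 2:
            raise ValueError("network needs at least 2 nodes")
        if any(u == v for u, v in graph.edges):
            raise ValueError("self-loops are not allowed")
        self.graph = graph
        self._strength = None
        self._adjacency = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges(self):
        return self.graph.edges

    def neighbors(self, i: int):
        return self.graph.neighbors(i)

    def tie_strength(self, i: int, j: int) -> float:
        return float(self.graph[i][j]["strength"])

    def _invalidate(self) -> None:
        self._strength = None
        self._adjacency = None

    @property
    def strength_matrix(self) -> sp.csr_array:
        """Symmetric CSR matrix of tie strengths."""
        if self._strength is None:
            self._strength = sp.csr_array(
                nx.to_scipy_sparse_array(
                    self.graph, nodelist=range(self.n_nodes), weight="strength"
                )
            )
        return self._strength

    @property
    def adjacency_matrix(self) -> sp.csr_array:
        """Symmetric 0/1 CSR adjacency."""
        if self._adjacency is None:
            a = self.strength_matrix.copy()
            a.data = np.ones_like(a.data)
            self._adjacency = a
        return self._adjacency

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency_matrix.sum(axis=1)).ravel()

    def write_edgelist(self, path) -> None:
        """Whitespace-delimited (node_i, node_j, S_ij) export."""
        with open(path, "w") as fh:
            for u, v, s in self.graph.edges(data="strength"):
                fh.write(f"{u} {v} {s:.10g}\n")


def _make_graph(kind: str, n: int, params: dict, seed: int) -> nx.Graph:
    if kind == "ba":
        m = int(params["m"])
        if m < 1 or m >= n:
            raise ValueError("BA attachment count m must satisfy 1 <= m < n")
        return nx.barabasi_albert_graph(n, m, seed=seed)
    if kind == "ws":
        k, p = int(params["k"]), float(params["p"])
        if k % 2 or k < 2 or k >= n:
            raise ValueError("WS neighbor count k must be even with 2 <= k < n")
        if not 0 <= p <= 1:
            raise ValueError("WS rewiring probability must be in [0, 1]")
        return nx.watts_strogatz_graph(n, k, p, seed=seed)
    if kind == "er":
        p = float(params["p"])
        if not 0 < p <= 1:
            raise ValueError("ER edge probability must be in (0, 1]")
        return nx.gnp_random_graph(n, p, seed=seed)
    if kind == "complete":
        return nx.complete_graph(n)
    raise ValueError(f"unknown network kind {kind!r}; expected ba, ws, er or complete")


def generate_network(
    kind: str,
    n: int,
    params: dict | None = None,
    rng: np.random.Generator | None = None,
    tie_spec: TraitSpec = DEFAULT_TIE_SPEC,
) -> SocialNetwork:
    """Generate a connected topology of the requested family with tie strengths.

    Disconnected draws are rejected and resampled (at most 100 times): the
    mean shortest-path length must be finite. ``kind`` is one of ``ba``
    (scale-free preferential attachment), ``ws`` (small-world ring rewiring),
    ``er`` (Erdos-Renyi random) or ``complete``.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    kind = kind.lower()
    if kind not in DEFAULT_PARAMS:
        raise ValueError(f"unknown network kind {kind!r}; expected ba, ws, er or complete")
    merged = dict(DEFAULT_PARAMS[kind])
    merged.update(params or {})
    rng = np.random.default_rng() if rng is None else rng
    for _ in range(_MAX_RETRIES):
        seed = int(rng.integers(0, 2**31 - 1))
        g = _make_graph(kind, n, merged, seed)
        if nx.is_connected(g):
            net = SocialNetwork(g)
            assign_tie_strengths(net, tie_spec, rng)
            return net
    raise RuntimeError(f"failed to generate a connected {kind} graph in {_MAX_RETRIES} attempts")


def assign_tie_strengths(
    net: SocialNetwork,
    spec: TraitSpec = DEFAULT_TIE_SPEC,
    rng: np.random.Generator | None = None,
) -> SocialNetwork:
    """Assign a symmetric strength in (0, 1] to every edge (in place).

    Draws follow ``spec`` (clipped normal); draws clipped onto 0 are nudged
    to 1e-6 so every edge keeps a strictly positive strength.
    """
    if spec.lower < 0 or spec.upper > 1:
        raise ValueError("tie-strength spec must lie within (0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    strengths = spec.sample(net.n_edges, rng)
    strengths[strengths <= 0.0] = _EPS
    for (u, v), s in zip(net.graph.edges, strengths):
        net.graph[u][v]["strength"] = float(s)
    net._invalidate()
    return net


def topology_metrics(net: SocialNetwork) -> TopologyMetrics:
    """Unweighted mean shortest-path length, average local clustering, mean degree.

    Path lengths average over distinct ordered node pairs (BFS via scipy
    csgraph); local clustering of nodes with degree < 2 counts as 0 in the
    global average. Raises on disconnected graphs.
    """
    a = net.adjacency_matrix
    n = net.n_nodes
    dist = shortest_path(a, method="D", unweighted=True, directed=False)
    if np.isinf(dist).any():
        raise ValueError("graph is disconnected: average path length undefined")
    apl = dist.sum() / (n * (n - 1))

    dense = np.asarray(a.todense(), dtype=np.float64)
    deg = dense.sum(axis=1)
    triangles = ((dense @ dense) * dense).sum(axis=1)  # closed ordered wedges per node
    possible = deg * (deg - 1)
    local = np.divide(triangles, possible, out=np.zeros(n), where=possible > 0)
    return TopologyMetrics(
        avg_path_length=float(apl),
        clustering_coefficient=float(local.mean()),
        avg_degree=float(2 * net.n_edges / n),
    )
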