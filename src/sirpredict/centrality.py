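"""Node centralities and edge density, normalised to [0, 1].

Eight structural predictors per node record: seven centralities (degree,
eigenvector, PageRank, Katz, closeness, betweenness, coreness) plus the
graph-level edge density shared by all nodes of a graph.  The point of the
normalisations is cross-graph comparability — raw values from different
graphs of the same size must live on a common scale:

* degree, coreness: divided by the maximum possible value N - 1;
* betweenness: divided by the maximum possible pair count (N-1)(N-2)/2;
* closeness: (N-1) / sum of shortest-path distances, already in (0, 1];
* eigenvector, Katz: the per-graph vector is scaled to unit Euclidean norm;
* PageRank: the per-graph vector is scaled to sum to one;
* edge density: M/N (half the mean degree), divided by its maximum (N-1)/2.

PageRank here is the matrix form x = D (D - alpha A)^{-1} 1 with damping
alpha = 0.85; Katz is x = (I - alpha A)^{-1} 1 with attenuation alpha = 0.1,
valid whenever alpha < 1/lambda_1 (checked per graph).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .graphspace import Graph

__all__ = [
    "CentralityConfig",
    "FEATURE_NAMES",
    "degree_centrality",
    "eigenvector_centrality",
    "pagerank",
    "katz_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "coreness",
    "edge_density",
    "feature_table",
]

#: Column order of the per-node feature vector.
FEATURE_NAMES = (
    "degree",
    "eigenvector",
    "pagerank",
    "katz",
    "closeness",
    "betweenness",
    "coreness",
    "density",
)


@dataclass(frozen=True)
class CentralityConfig:
    pagerank_alpha: float = 0.85
    katz_alpha: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.pagerank_alpha < 1):
            raise ValueError("pagerank_alpha must be in (0, 1)")
        if self.katz_alpha <= 0:
            raise ValueError("katz_alpha must be positive")


def _adjacency(g: Graph) -> np.ndarray:
    a = np.zeros((g.n_nodes, g.n_nodes))
    for u, v in g.edges:
        a[u, v] = a[v, u] = 1.0
    return a


def degree_centrality(g: Graph) -> np.ndarray:
    """deg(i) / (N - 1); equals 1 only for a node adjacent to all others."""
    return np.asarray(g.degrees(), dtype=float) / (g.n_nodes - 1)


def eigenvector_centrality(
    g: Graph, *, tol: float = 1e-14, max_iter: int = 100_000
) -> np.ndarray:
    """Principal eigenvector of the adjacency matrix, unit 2-norm.

    Computed by power iteration on A + I; the shift makes the spectrum
    positive so the iteration converges on bipartite graphs too (where A's
    extreme eigenvalues come in a +/- pair).  For a connected graph the
    Perron vector is unique and strictly positive.
    """
    a = _adjacency(g) + np.eye(g.n_nodes)
    x = np.ones(g.n_nodes) / np.sqrt(g.n_nodes)
    for _ in range(max_iter):
        y = a @ x
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) < tol:
            return y
        x = y
    raise RuntimeError(
        f"eigenvector iteration did not converge in {max_iter} steps "
        f"(residual {np.linalg.norm(a @ x - (x @ a @ x) * x):.2e})"
    )


def _spectral_radius(g: Graph) -> float:
    x = eigenvector_centrality(g)
    a = _adjacency(g)
    return float(x @ a @ x)


def pagerank(g: Graph, config: CentralityConfig | None = None) -> np.ndarray:
    """x = D (D - alpha A)^{-1} 1, then normalised to sum to one."""
    config = config or CentralityConfig()
    a = _adjacency(g)
    d = np.diag(np.asarray(g.degrees(), dtype=float))
    x = d @ np.linalg.solve(d - config.pagerank_alpha * a, np.ones(g.n_nodes))
    return x / x.sum()


def katz_centrality(g: Graph, config: CentralityConfig | None = None) -> np.ndarray:
    """x = (I - alpha A)^{-1} 1, then normalised to unit 2-norm.

    Requires alpha * lambda_1 < 1 (at alpha = 0.1 this holds for every graph
    with at most 10 nodes, whose spectral radius is below 10)."""
    config = config or CentralityConfig()
    lam = _spectral_radius(g)
    if config.katz_alpha * lam >= 1:
        raise ValueError(
            f"katz_alpha={config.katz_alpha} >= 1/lambda_1={1 / lam:.4f}: "
            "the Katz series diverges for this graph"
        )
    a = _adjacency(g)
    x = np.linalg.solve(np.eye(g.n_nodes) - config.katz_alpha * a, np.ones(g.n_nodes))
    return x / np.linalg.norm(x)


def closeness_centrality(g: Graph) -> np.ndarray:
    """(N - 1) / sum_j d_ij over breadth-first shortest-path distances."""
    c = nx.closeness_centrality(g.to_networkx())
    return np.array([c[i] for i in range(g.n_nodes)])


def betweenness_centrality(g: Graph) -> np.ndarray:
    """Sum over unordered pairs j < k (excluding i) of the fraction of
    shortest j-k paths through i, divided by the pair count (N-1)(N-2)/2."""
    c = nx.betweenness_centrality(g.to_networkx(), normalized=True)
    return np.array([c[i] for i in range(g.n_nodes)])


def coreness(g: Graph) -> np.ndarray:
    """Largest k such that node i belongs to a k-core, divided by N - 1."""
    c = nx.core_number(g.to_networkx())
    return np.array([c[i] for i in range(g.n_nodes)], dtype=float) / (g.n_nodes - 1)


def edge_density(g: Graph) -> float:
    """M/N rescaled by its maximum (N-1)/2, i.e. 2M / (N(N-1)) in (0, 1]."""
    n = g.n_nodes
    return 2.0 * g.n_edges / (n * (n - 1))


def feature_table(
    graphs: Iterable[Graph], config: CentralityConfig | None = None
) -> pd.DataFrame:
    """All eight predictors for every node of every graph.

    Columns: graph_id, node, then :data:`FEATURE_NAMES` in order.
    """
    config = config or CentralityConfig()
    rows = []
    for g in graphs:
        cols = {
            "degree": degree_centrality(g),
            "eigenvector": eigenvector_centrality(g),
            "pagerank": pagerank(g, config),
            "katz": katz_centrality(g, config),
            "closeness": closeness_centrality(g),
            "betweenness": betweenness_centrality(g),
            "coreness": coreness(g),
        }
        dens = edge_density(g)
        for i in range(g.n_nodes):
            rows.append(
                (g.graph_id, i)
                + tuple(cols[name][i] for name in FEATURE_NAMES[:-1])
                + (dens,)
            )
    return pd.DataFrame(rows, columns=["graph_id", "node", *FEATURE_NAMES])
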