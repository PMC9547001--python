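"""Eigenvector-centrality simplification of metabolic graphs.

Genome-scale metabolite graphs have thousands of nodes; for many
analyses a sub-network of the structurally most important metabolites is
enough. Importance is measured by eigenvector centrality — a node scores
high when its neighbours score high, i.e. the score vector is the
principal eigenvector of the adjacency matrix. The simplified network is
the subgraph induced by the top-k ranked nodes, with nodes isolated by
the cut removed (so the retained count may fall below k).

Centrality is computed on the weight-symmetrised undirected projection
of the graph (the weight of {u, v} is the sum of the two directed
weights): on directed graphs that are not strongly connected the
principal eigenvector is not well defined, while the symmetrised
adjacency always has a unique non-negative one per dominant component
(Perron-Frobenius).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .exceptions import ConvergenceError, EmptyGraphError

__all__ = ["CentralityRanking", "eigen_centrality", "select_subnetwork"]


@dataclass(frozen=True)
class CentralityRanking:
    """Eigenvector-centrality scores, max-normalised to [0, 1].

    ``order`` ranks nodes by decreasing score with lexicographic
    tie-break, so ``order[:k]`` is the deterministic top-k set.
    """

    scores: dict[str, float]
    order: tuple[str, ...]

    def top(self, k: int) -> tuple[str, ...]:
        return self.order[:k]


def eigen_centrality(
    graph: nx.Graph,
    use_weights: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> CentralityRanking:
    """Principal-eigenvector scores of the symmetrised adjacency.

    Power iteration on the dense symmetric matrix, uniform start vector,
    infinity-norm convergence test; scores are divided by their maximum
    so the most central node scores exactly 1. Scores are invariant to a
    global positive rescaling of the edge weights.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise EmptyGraphError("cannot rank an empty graph")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        if u == v:
            continue
        w = float(data.get("weight", 1.0)) if use_weights else 1.0
        if w < 0:
            raise ValueError(f"negative edge weight on {u} -> {v}")
        adj[index[u], index[v]] += w
        adj[index[v], index[u]] += w
    if not adj.any():
        raise ConvergenceError(
            "adjacency is all-zero (no edges or all weights 0); "
            "eigenvector centrality is undefined"
        )
    x = np.full(n, 1.0 / n)
    # iterate with A + I: same eigenvectors, but the spectral shift breaks
    # the +/-lambda oscillation on bipartite graphs (stars, chains)
    for _ in range(max_iter):
        nxt = adj @ x + x
        norm = np.linalg.norm(nxt)
        if norm == 0:
            raise ConvergenceError("power iteration collapsed to zero vector")
        nxt /= norm
        if np.max(np.abs(nxt - x)) < tol:
            x = nxt
            break
        x = nxt
    else:
        raise ConvergenceError(
            f"power iteration did not reach tolerance {tol} in "
            f"{max_iter} iterations"
        )
    x = np.abs(x)
    scores = {node: float(s) for node, s in zip(nodes, x / x.max())}
    order = tuple(sorted(nodes, key=lambda n: (-scores[n], n)))
    return CentralityRanking(scores=scores, order=order)


def select_subnetwork(graph: nx.Graph, ranking: CentralityRanking, k: int) -> nx.Graph:
    """Subgraph induced by the top-k central nodes, isolates removed.

    Edges (and their weights and annotations) are inherited unchanged
    from the input graph; the result may have fewer than k nodes.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > graph.number_of_nodes():
        raise ValueError(
            f"k={k} exceeds the node count {graph.number_of_nodes()}"
        )
    keep = ranking.top(k)
    sub = graph.subgraph(keep).copy()
    sub.remove_nodes_from(list(nx.isolates(sub)))
    if sub.number_of_nodes() == 0:
        raise EmptyGraphError(
            f"top-{k} selection left no connected nodes"
        )
    return sub
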