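"""Transition-matrix representation and Jensen-Shannon network distance.

A graph over a node ordering of length *l* is represented by its
one-step **transition matrix** T (l x l, row-stochastic): row i is the
probability distribution of the next position of a random walker
currently at node i — out-edge weights normalised to sum 1, or uniform
over out-neighbours for unweighted graphs. Each row thus summarises the
local connectivity of one node.

Two graphs sharing the node ordering are compared by averaging, over the
l nodes, the Jensen-Shannon distance between the corresponding rows::

    M(Gp, Gq) = (1 / l) * sum_i  d_JS(Tp_i, Tq_i)

d_JS is the square root of the Jensen-Shannon divergence with base-2
logarithms, a metric bounded by 1; M therefore lies in [0, 1], is
symmetric, vanishes iff the transition matrices coincide, and — because
normalisation cancels any global factor — is invariant under a positive
rescaling of all edge weights.

Nodes with no out-edge (or with total out-weight 0, e.g. when every
incident reaction lacks a GPR), and nodes of the shared ordering absent
from a particular graph, need a *dangling* fallback row: by default a
unit mass on the node itself, which keeps the row local; a uniform
distribution over all nodes is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TransitionMatrix",
    "DistanceMatrix",
    "transition_matrix",
    "js_distance",
    "network_distance",
    "gram_matrix",
    "shared_node_order",
]

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic one-step random-walk matrix over ``node_order``."""

    node_order: tuple[str, ...]
    matrix: np.ndarray  # shape (l, l), rows sum to 1

    def __post_init__(self) -> None:
        l = len(self.node_order)
        if self.matrix.shape != (l, l):
            raise ValueError("matrix shape does not match node_order")
        if (self.matrix < 0).any():
            raise ValueError("transition matrix has negative entries")
        sums = self.matrix.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > _ROW_TOL:
            raise ValueError("transition-matrix rows must sum to 1")

    def row(self, node_id: str) -> np.ndarray:
        return self.matrix[self.node_order.index(node_id)]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise network-distance (Gram) matrix."""

    graph_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.graph_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match graph_ids")

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.graph_ids)
        return pd.DataFrame(self.matrix, index=ids, columns=ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DistanceMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("distance matrix must have matching row/column ids")
        return cls(tuple(str(i) for i in frame.index), frame.to_numpy(dtype=float))


def shared_node_order(graphs: Sequence[nx.Graph]) -> tuple[str, ...]:
    """Sorted union of the node sets of a graph collection."""
    nodes: set[str] = set()
    for g in graphs:
        nodes.update(g.nodes)
    return tuple(sorted(nodes))


def transition_matrix(
    graph: nx.Graph,
    node_order: Sequence[str],
    dangling: str = "self",
) -> TransitionMatrix:
    """One-step transition matrix of ``graph`` over ``node_order``.

    Row i is the out-edge weight distribution of node i (edges without a
    ``weight`` attribute count 1, so unweighted graphs walk uniformly
    over out-neighbours). Rows for dangling nodes — zero out-weight or
    absent from the graph — follow ``dangling``: ``"self"`` puts unit
    mass on the node itself, ``"uniform"`` spreads it over all nodes.
    """
    if dangling not in ("self", "uniform"):
        raise ValueError(f"unknown dangling policy {dangling!r}")
    order = tuple(node_order)
    index = {n: i for i, n in enumerate(order)}
    missing = set(graph.nodes) - set(order)
    if missing:
        raise ValueError(
            f"graph nodes not in node_order: {sorted(missing)[:5]}"
        )
    l = len(order)
    T = np.zeros((l, l))
    out_edges = graph.out_edges if graph.is_directed() else graph.edges
    for i, node in enumerate(order):
        if node in graph:
            for _, v, data in out_edges(node, data=True):
                w = float(data.get("weight", 1.0))
                if w < 0:
                    raise ValueError(f"negative weight on edge {node} -> {v}")
                T[i, index[v]] += w
        total = T[i].sum()
        if total > 0:
            T[i] /= total
        elif dangling == "self":
            T[i, i] = 1.0
        else:
            T[i] = 1.0 / l
    return TransitionMatrix(node_order=order, matrix=T)


def js_distance(p: np.ndarray, q: np.ndarray, tol: float = 1e-6) -> float:
    """Jensen-Shannon distance between two probability vectors.

    sqrt(JSD) with base-2 logarithms, so the value lies in [0, 1] and
    reaches 1 exactly for distributions with disjoint support. The
    convention 0 * log 0 = 0 applies.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probability vectors must be non-negative")
    if abs(p.sum() - 1.0) > tol or abs(q.sum() - 1.0) > tol:
        raise ValueError("probability vectors must each sum to 1")
    m = 0.5 * (p + q)
    # 0*log 0 := 0; where m == 0 both p and q are 0, so the ratio is unused
    ratio_p = np.divide(p, m, out=np.ones_like(p), where=m > 0)
    ratio_q = np.divide(q, m, out=np.ones_like(q), where=m > 0)
    kl_pm = np.where(p > 0, p * np.log2(np.where(ratio_p > 0, ratio_p, 1.0)), 0.0)
    kl_qm = np.where(q > 0, q * np.log2(np.where(ratio_q > 0, ratio_q, 1.0)), 0.0)
    jsd = 0.5 * kl_pm.sum() + 0.5 * kl_qm.sum()
    return float(np.sqrt(max(jsd, 0.0)))


def network_distance(Tp: TransitionMatrix, Tq: TransitionMatrix) -> float:
    """Average row-wise Jensen-Shannon distance between two transition
    matrices sharing a node ordering."""
    if Tp.node_order != Tq.node_order:
        raise ValueError(
            "transition matrices have different node orderings; build both "
            "on the union node set (see shared_node_order)"
        )
    l = len(Tp.node_order)
    return float(
        sum(js_distance(Tp.matrix[i], Tq.matrix[i]) for i in range(l)) / l
    )


def gram_matrix(
    graphs: Sequence[nx.Graph],
    node_order: Sequence[str] | None = None,
    dangling: str = "self",
    graph_ids: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All pairwise network distances of a graph collection.

    ``node_order`` defaults to the sorted union of all node sets; for
    collections sharing one structure (graphs from a single tissue
    model) this equals each graph's own node set, while for collections
    with differing structures absent nodes enter as dangling rows.
    """
    if len(graphs) < 2:
        raise ValueError("need at least two graphs")
    if node_order is None:
        node_order = shared_node_order(graphs)
    if graph_ids is None:
        graph_ids = [
            str(g.graph.get("graph_id", f"graph{i}")) for i, g in enumerate(graphs)
        ]
    if len(graph_ids) != len(graphs):
        raise ValueError("graph_ids length must match graphs")
    mats = [transition_matrix(g, node_order, dangling=dangling) for g in graphs]
    n = len(graphs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = network_distance(mats[i], mats[j])
    return DistanceMatrix(graph_ids=tuple(graph_ids), matrix=D)
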