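"""Construction of metabolite-, enzyme- and reaction-based graphs.

All builders return networkx graphs following one attribute convention
(referred to as a *MetGraph* throughout the package):

* graph attributes: ``graph_id`` (model or sample id), ``node_kind``
  (``"metabolite"`` | ``"enzyme"`` | ``"reaction"``), ``weighted`` (bool);
* node attribute ``label``;
* edge attributes ``reactions`` and ``enzymes`` (tuples of ids; may be
  empty) and, after weighting, ``weight`` (non-negative float).

The three graph types encode complementary views of the same model:

* **metabolite graph** — metabolites as nodes, a directed edge
  reactant -> product for every reactant/product pair of a reaction;
* **enzyme graph** — enzyme complexes (AND-conjuncts of each reaction's
  GPR; isozymes split by OR) as nodes, an edge when one complex's
  reaction produces a metabolite another complex's reaction consumes;
* **reaction graph** — reactions as nodes, an edge when one produces a
  metabolite the other consumes.

Recurrent (currency) metabolites such as ATP or H2O are excluded from
every pairing, because their ubiquity would otherwise create shortcut
paths with no biochemical meaning. Self-loops, duplicate edges and
isolated nodes never survive construction; :func:`validate_structure`
re-checks those invariants on any graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .exceptions import EmptyGraphError, GraphConstructionWarning
from .model_io import (
    ExpressionTable,
    MetabolicModel,
    ReactionRecord,
    RecurrentSet,
    gpr_to_dnf,
)

__all__ = [
    "build_metabolite_graph",
    "weight_and_simplify",
    "collapse_to_simple",
    "build_enzyme_graph",
    "build_reaction_graph",
    "validate_structure",
    "Violation",
]


def _dedup(ids: Iterable[str]) -> tuple[str, ...]:
    return tuple(dict.fromkeys(ids))


def _role_sides(
    rxn: ReactionRecord, double_reversible: bool
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """(consumed, produced) species-id pairs for each active direction.

    The written direction is always active; a reversible reaction also
    contributes the mirrored direction when ``double_reversible``.
    """
    sides = [(_dedup(rxn.reactant_ids), _dedup(rxn.product_ids))]
    if double_reversible and rxn.reversible:
        sides.append((_dedup(rxn.product_ids), _dedup(rxn.reactant_ids)))
    return sides


def _keep(model: MetabolicModel, recurrent: RecurrentSet | None, sid: str) -> bool:
    return recurrent is None or not recurrent.matches(model.species[sid])


# ---------------------------------------------------------------------------
# metabolite graphs
# ---------------------------------------------------------------------------


def build_metabolite_graph(
    model: MetabolicModel,
    recurrent: RecurrentSet | None = None,
    double_reversible: bool = False,
    graph_id: str | None = None,
) -> nx.MultiDiGraph:
    """Metabolites as nodes; one directed edge per (reactant, product)
    pair per reaction.

    Returns an unweighted *multigraph*: the same node pair may be linked
    by several reactions, and :func:`weight_and_simplify` later collapses
    the parallel edges. Each edge carries the reaction id and the flat
    list of genes of that reaction's GPR (the catalysing enzymes), when
    present. Recurrent species are removed from both sides of every
    reaction before pairing; self-loops (a species on both sides) are
    never emitted and nodes that end up with no edges are not included.
    """
    graph = nx.MultiDiGraph(
        graph_id=graph_id or model.model_id,
        node_kind="metabolite",
        weighted=False,
    )
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        genes = rxn.gpr.genes() if rxn.gpr is not None else ()
        for consumed, produced in _role_sides(rxn, double_reversible):
            rs = [s for s in consumed if _keep(model, recurrent, s)]
            ps = [s for s in produced if _keep(model, recurrent, s)]
            for r in rs:
                for p in ps:
                    if r == p:
                        continue
                    graph.add_edge(r, p, reaction=rid, enzymes=genes)
    if graph.number_of_edges() == 0:
        raise EmptyGraphError(
            f"model {model.model_id!r}: no metabolite edges remain "
            "(all pairs suppressed or no valid reactant/product pairs)"
        )
    for node in graph.nodes:
        graph.nodes[node]["label"] = node
    return graph


def weight_and_simplify(
    graph: nx.MultiDiGraph,
    expr: ExpressionTable,
    sample_id: str,
    missing_policy: str = "skip",
) -> nx.DiGraph:
    """Collapse a metabolite multigraph into a weighted simple digraph.

    Parallel edges between one node pair arise from different reactions
    (and from multiple enzymes within a reaction, already flattened into
    the edge's gene list). Weighting follows a mean-then-sum rule: the
    weight contributed by one reaction is the mean expression of its
    genes in ``sample_id``, and the final weight of a (source, target)
    pair is the sum of those per-reaction means.

    ``missing_policy`` controls genes absent from the expression table:
    ``"skip"`` drops them from the mean's denominator, ``"zero"`` counts
    them as 0. A reaction with no GPR (or, under ``"skip"``, with no
    measured gene at all) contributes weight 0 but its edges are kept:
    the topology is model-determined, only the weights are
    sample-determined.
    """
    if missing_policy not in ("skip", "zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if sample_id not in expr.samples:
        raise KeyError(f"sample {sample_id!r} not in expression table")

    warned: set[str] = set()

    def reaction_mean(edge_data: dict) -> float:
        genes = edge_data["enzymes"]
        if not genes:
            return 0.0
        values = [expr.value(g, sample_id) for g in genes]
        if missing_policy == "zero":
            values = [0.0 if v is None else v for v in values]
        else:
            values = [v for v in values if v is not None]
            if not values:
                rid = edge_data["reaction"]
                if rid not in warned:
                    warned.add(rid)
                    warnings.warn(
                        f"reaction {rid}: no gene of its GPR is in the "
                        "expression table; contributes weight 0",
                        GraphConstructionWarning,
                        stacklevel=3,
                    )
                return 0.0
        return float(sum(values)) / len(values)

    simple = nx.DiGraph(
        graph_id=sample_id,
        node_kind="metabolite",
        weighted=True,
        source_model=graph.graph.get("graph_id", ""),
    )
    for u, v, data in graph.edges(data=True):
        mean = reaction_mean(data)
        if simple.has_edge(u, v):
            edge = simple.edges[u, v]
            edge["weight"] += mean
            edge["reactions"] = edge["reactions"] + (data["reaction"],)
            edge["enzymes"] = edge["enzymes"] + tuple(data["enzymes"])
        else:
            simple.add_edge(
                u,
                v,
                weight=mean,
                reactions=(data["reaction"],),
                enzymes=tuple(data["enzymes"]),
            )
    for _, _, edge in simple.edges(data=True):
        edge["reactions"] = tuple(sorted(set(edge["reactions"])))
        edge["enzymes"] = tuple(sorted(set(edge["enzymes"])))
    for node in simple.nodes:
        simple.nodes[node]["label"] = graph.nodes[node].get("label", node)
    return simple


def collapse_to_simple(graph: nx.MultiDiGraph) -> nx.DiGraph:
    """Merge parallel edges of a metabolite multigraph without weighting.

    Annotation lists (reactions, enzymes) are unioned and sorted; the
    result is an unweighted simple digraph suitable for export.
    """
    simple = nx.DiGraph(**graph.graph)
    simple.graph["weighted"] = False
    for u, v, data in graph.edges(data=True):
        if simple.has_edge(u, v):
            edge = simple.edges[u, v]
            edge["reactions"] = edge["reactions"] + (data["reaction"],)
            edge["enzymes"] = edge["enzymes"] + tuple(data["enzymes"])
        else:
            simple.add_edge(
                u, v, reactions=(data["reaction"],), enzymes=tuple(data["enzymes"])
            )
    for _, _, edge in simple.edges(data=True):
        edge["reactions"] = tuple(sorted(set(edge["reactions"])))
        edge["enzymes"] = tuple(sorted(set(edge["enzymes"])))
    for node in simple.nodes:
        simple.nodes[node]["label"] = graph.nodes[node].get("label", node)
    return simple


# ---------------------------------------------------------------------------
# enzyme and reaction graphs
# ---------------------------------------------------------------------------


def _producers_consumers(
    model: MetabolicModel,
    recurrent: RecurrentSet | None,
    double_reversible: bool,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Non-recurrent species -> producing / consuming reaction ids."""
    producers: dict[str, set[str]] = {}
    consumers: dict[str, set[str]] = {}
    for rid, rxn in model.reactions.items():
        for consumed, produced in _role_sides(rxn, double_reversible):
            for s in consumed:
                if _keep(model, recurrent, s):
                    consumers.setdefault(s, set()).add(rid)
            for s in produced:
                if _keep(model, recurrent, s):
                    producers.setdefault(s, set()).add(rid)
    return producers, consumers


def build_enzyme_graph(
    model: MetabolicModel,
    recurrent: RecurrentSet | None = None,
    double_reversible: bool = False,
    graph_id: str | None = None,
) -> nx.DiGraph:
    """Enzyme complexes as nodes; an edge c1 -> c2 when a reaction
    catalysed by c1 produces a non-recurrent metabolite consumed by a
    reaction catalysed by c2.

    Nodes come from the disjunctive normal form of each reaction's GPR:
    genes related by AND form a single complex node (label: sorted genes
    joined with ``_AND_``), OR-alternatives become separate nodes.
    Reactions without a GPR contribute no nodes and therefore break
    paths running through them. Self-loops are removed and complexes
    that end up without edges are dropped.
    """
    complexes: dict[str, list[str]] = {}
    for rid, rxn in model.reactions.items():
        if rxn.gpr is not None:
            complexes[rid] = [c.label for c in gpr_to_dnf(rxn.gpr)]
    if not complexes:
        raise EmptyGraphError(
            f"model {model.model_id!r} has no reaction with a GPR; "
            "enzyme graph is empty"
        )
    producers, consumers = _producers_consumers(model, recurrent, double_reversible)
    graph = nx.DiGraph(
        graph_id=graph_id or model.model_id,
        node_kind="enzyme",
        weighted=False,
    )
    for species in sorted(set(producers) & set(consumers)):
        for r1 in producers[species]:
            for r2 in consumers[species]:
                for c1 in complexes.get(r1, ()):
                    for c2 in complexes.get(r2, ()):
                        if c1 == c2:
                            continue
                        if graph.has_edge(c1, c2):
                            edge = graph.edges[c1, c2]
                            edge["reactions"] = edge["reactions"] | {(r1, r2)}
                        else:
                            graph.add_edge(c1, c2, reactions={(r1, r2)})
    if graph.number_of_edges() == 0:
        raise EmptyGraphError(
            f"model {model.model_id!r}: no enzyme-enzyme connections remain"
        )
    for _, _, edge in graph.edges(data=True):
        edge["reactions"] = tuple(sorted({r for pair in edge["reactions"] for r in pair}))
        edge["enzymes"] = ()
    for node in graph.nodes:
        graph.nodes[node]["label"] = node
    return graph


def build_reaction_graph(
    model: MetabolicModel,
    recurrent: RecurrentSet | None = None,
    double_reversible: bool = False,
    graph_id: str | None = None,
) -> nx.DiGraph:
    """Reactions as nodes; an edge R1 -> R2 (R1 != R2) when R1 produces a
    non-recurrent metabolite that R2 consumes."""
    producers, consumers = _producers_consumers(model, recurrent, double_reversible)
    graph = nx.DiGraph(
        graph_id=graph_id or model.model_id,
        node_kind="reaction",
        weighted=False,
    )
    for species in sorted(set(producers) & set(consumers)):
        for r1 in producers[species]:
            for r2 in consumers[species]:
                if r1 == r2:
                    continue
                graph.add_edge(r1, r2)
    if graph.number_of_edges() == 0:
        raise EmptyGraphError(
            f"model {model.model_id!r}: no reaction-reaction connections "
            "remain (all nodes isolated)"
        )
    for u, v in graph.edges:
        graph.edges[u, v]["reactions"] = (u, v)
        graph.edges[u, v]["enzymes"] = ()
    for node in graph.nodes:
        graph.nodes[node]["label"] = node
    return graph


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One structural defect found by :func:`validate_structure`."""

    kind: str  # "self-loop" | "duplicate-edge" | "isolated-node" | "dangling-endpoint"
    detail: str


def validate_structure(graph: nx.Graph) -> list[Violation]:
    """Report self-loops, duplicate edges, isolated nodes and edges whose
    endpoints are missing from the node list. Clean graphs return []."""
    violations: list[Violation] = []
    for u, v in nx.selfloop_edges(graph):
        violations.append(Violation("self-loop", f"{u} -> {v}"))
    if graph.is_multigraph():
        seen: set[tuple[str, str]] = set()
        for u, v, _ in graph.edges(keys=True):
            if (u, v) in seen:
                violations.append(Violation("duplicate-edge", f"{u} -> {v}"))
            seen.add((u, v))
    for node in nx.isolates(graph):
        violations.append(Violation("isolated-node", str(node)))
    nodes = set(graph.nodes)
    for u, v in graph.edges():
        for endpoint in (u, v):
            if endpoint not in nodes:  # unreachable with networkx, kept as a guard
                violations.append(Violation("dangling-endpoint", str(endpoint)))
    return violations
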