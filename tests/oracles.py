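"""Independent brute-force implementations used as test oracles.

Everything here is written from the construction rules directly —
nested loops over reactions and species pairs, truth-table enumeration
for boolean gene rules — without reusing any metnet graph-building
code, so agreement with the package is meaningful.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import combinations

from metnet.model_io import GPRTree, MetabolicModel, RecurrentSet


def recurrent_ids(model: MetabolicModel, recurrent: RecurrentSet | None) -> set[str]:
    if recurrent is None:
        return set()
    return {sid for sid, sp in model.species.items() if recurrent.matches(sp)}


def directions(rxn, double_reversible: bool):
    """(consumed, produced) species lists for each active direction."""
    dirs = [(list(rxn.reactant_ids), list(rxn.product_ids))]
    if double_reversible and rxn.reversible:
        dirs.append((list(rxn.product_ids), list(rxn.reactant_ids)))
    return dirs


def brute_metabolite_edges(model, recurrent, double_reversible=False):
    """Reactant -> product pairs per reaction, recurrent pairs and
    self-loops excluded."""
    skip = recurrent_ids(model, recurrent)
    edges = set()
    for rxn in model.reactions.values():
        for consumed, produced in directions(rxn, double_reversible):
            for r in consumed:
                for p in produced:
                    if r != p and r not in skip and p not in skip:
                        edges.add((r, p))
    return edges


def minimal_true_sets(tree: GPRTree) -> set[frozenset[str]]:
    """Prime implicants of a monotone boolean gene rule, by exhaustive
    truth-table enumeration over all subsets of its genes."""
    genes = list(tree.genes())
    satisfying = [
        frozenset(sub)
        for k in range(len(genes) + 1)
        for sub in combinations(genes, k)
        if tree.evaluate(sub)
    ]
    return {
        s for s in satisfying if not any(t < s for t in satisfying)
    }


def brute_enzyme_edges(model, recurrent, double_reversible=False):
    """Complex-label pairs: c1 -> c2 when a reaction of c1 produces a
    non-recurrent species that a reaction of c2 consumes."""
    skip = recurrent_ids(model, recurrent)
    complexes = {
        rid: ["_AND_".join(sorted(s)) for s in minimal_true_sets(rxn.gpr)]
        for rid, rxn in model.reactions.items()
        if rxn.gpr is not None
    }
    produced_by = defaultdict(set)
    consumed_by = defaultdict(set)
    for rid, rxn in model.reactions.items():
        for consumed, produced in directions(rxn, double_reversible):
            for s in consumed:
                if s not in skip:
                    consumed_by[s].add(rid)
            for s in produced:
                if s not in skip:
                    produced_by[s].add(rid)
    edges = set()
    for s in produced_by:
        for r1 in produced_by[s]:
            for r2 in consumed_by.get(s, ()):
                for c1 in complexes.get(r1, ()):
                    for c2 in complexes.get(r2, ()):
                        if c1 != c2:
                            edges.add((c1, c2))
    return edges


def brute_reaction_edges(model, recurrent, double_reversible=False):
    skip = recurrent_ids(model, recurrent)
    edges = set()
    for r1, rxn1 in model.reactions.items():
        for r2, rxn2 in model.reactions.items():
            if r1 == r2:
                continue
            for _, produced in directions(rxn1, double_reversible):
                for consumed, _ in directions(rxn2, double_reversible):
                    if any(
                        s in consumed and s not in skip for s in produced
                    ):
                        edges.add((r1, r2))
    return edges


def brute_edge_weights(
    model, recurrent, expr, sample_id, double_reversible=False,
    missing_policy="skip",
):
    """Mean-per-reaction-then-sum-per-pair edge weights, accumulated
    directly from the model."""
    skip = recurrent_ids(model, recurrent)
    weights: dict[tuple[str, str], float] = defaultdict(float)
    for rxn in model.reactions.values():
        genes = list(rxn.gpr.genes()) if rxn.gpr is not None else []
        values = []
        for g in genes:
            v = expr.value(g, sample_id)
            if v is None and missing_policy == "zero":
                v = 0.0
            if v is not None:
                values.append(v)
        mean = sum(values) / len(values) if values else 0.0
        for consumed, produced in directions(rxn, double_reversible):
            for r in consumed:
                for p in produced:
                    if r != p and r not in skip and p not in skip:
                        weights[(r, p)] += mean
    return dict(weights)
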