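"""Shared fixtures and helpers for the metnet test suite."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metnet.model_io import (
    ExpressionTable,
    MetabolicModel,
    ReactionRecord,
    SpeciesRecord,
    parse_gpr,
)

settings.register_profile(
    "suite",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def hand_model(reactions, model_id="hand"):
    """Build a MetabolicModel from (rid, reactants, products, gpr_rule,
    reversible) tuples; species records are created on the fly with the
    species id doubling as the display name."""
    species: dict[str, SpeciesRecord] = {}
    recs: dict[str, ReactionRecord] = {}
    for rid, reactants, products, rule, reversible in reactions:
        for sid in list(reactants) + list(products):
            species.setdefault(sid, SpeciesRecord(sid, sid, "c"))
        recs[rid] = ReactionRecord(
            reaction_id=rid,
            reversible=reversible,
            reactants=tuple((s, 1.0) for s in reactants),
            products=tuple((s, 1.0) for s in products),
            gpr=parse_gpr(rule) if rule else None,
        )
    return MetabolicModel(model_id=model_id, species=species, reactions=recs)


def expr_table(data: dict[str, dict[str, float]]) -> ExpressionTable:
    """ExpressionTable from {gene: {sample: value}}."""
    return ExpressionTable(pd.DataFrame(data).T)


@pytest.fixture
def linear_chain_model():
    """A -> B -> C with simple GPRs; the running example of the metabolite
    graph rules."""
    return hand_model(
        [
            ("R1", ["A"], ["B"], "g1", False),
            ("R2", ["B"], ["C"], "g1 or g2", False),
        ]
    )
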