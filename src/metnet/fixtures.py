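"""Synthetic metabolic models and expression populations.

Real inputs to this package are genome-scale metabolic models (SBML) and
RNA-seq expression tables, both large downloads. This module generates
miniature stand-ins with known ground truth so that every pipeline stage
can be exercised and tested offline:

* :func:`make_model` draws a random toy model — a spanning chain of
  reactions guaranteeing a weakly connected metabolite graph, plus
  random extra reactions, random boolean GPRs over an Ensembl-style gene
  pool, a configurable fraction of reversible reactions, and a set of
  currency species (named after real recurrent metabolites such as ATP
  and H2O so the built-in recurrent list matches them);
* :func:`model_to_sbml` / :func:`write_sbml` serialise any
  :class:`~metnet.model_io.MetabolicModel` to SBML Level 3 + fbc,
  byte-deterministically, round-tripping through
  :func:`~metnet.model_io.parse_model`;
* :func:`make_population` layers class structure on top: per-sample
  expression = lognormal baseline per gene, plus an additive class
  effect (log-space shift ``weight_shift``) on class-specific disjoint
  signature genes, plus Gaussian noise — emulating cohorts whose graphs
  share one topology but differ in expression-derived edge weights.

Everything is driven by explicit integer seeds; equal seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import libsbml
import numpy as np
import pandas as pd

from .classify import LabeledCollection
from .model_io import (
    ENSEMBL_ID_RE,
    ExpressionTable,
    GPRTree,
    MetabolicModel,
    ReactionRecord,
    SpeciesRecord,
    _combine,
    _gene,
)

__all__ = [
    "ToyModelSpec",
    "ClassedPopulationSpec",
    "ClassedPopulation",
    "make_model",
    "make_population",
    "model_to_sbml",
    "write_sbml",
]

# currency species available to the generator; names match the built-in
# recurrent list of model_io
_CURRENCY_NAMES = ("ATP", "H2O", "CO2", "NADH", "ADP", "O2", "Pi", "NH3", "CoA", "NADPH")


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of one random toy model."""

    n_species: int = 20
    n_reactions: int = 30
    reversible_fraction: float = 0.25
    gpr_gene_pool: int = 15
    max_genes_per_reaction: int = 4
    recurrent_fraction: float = 0.15
    gpr_probability: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_reactions, self.gpr_gene_pool) <= 0:
            raise ValueError("counts must be positive")
        if self.max_genes_per_reaction <= 0:
            raise ValueError("max_genes_per_reaction must be positive")
        for frac in (self.reversible_fraction, self.recurrent_fraction, self.gpr_probability):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        n_recurrent = round(self.recurrent_fraction * self.n_species)
        if self.n_species - n_recurrent < 2:
            raise ValueError(
                "spec infeasible: fewer than 2 non-recurrent species "
                f"({self.n_species} species, {n_recurrent} recurrent)"
            )


def _gene_pool(size: int) -> list[str]:
    genes = [f"ENSG{i + 1:011d}" for i in range(size)]
    assert all(ENSEMBL_ID_RE.match(g) for g in genes)
    return genes


def _random_gpr(rng: np.random.Generator, pool: list[str], max_genes: int) -> GPRTree:
    n = int(rng.integers(1, max_genes + 1))
    genes = [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]
    if n == 1:
        return _gene(genes[0])
    shape = rng.choice(["and", "or", "mixed"]) if n >= 3 else rng.choice(["and", "or"])
    leaves = [_gene(g) for g in genes]
    if shape == "and":
        return _combine("AND", leaves)
    if shape == "or":
        return _combine("OR", leaves)
    cut = int(rng.integers(2, n))  # first conjunct gets >= 2 genes
    left = _combine("AND", leaves[:cut])
    right = _combine("AND", leaves[cut:]) if n - cut > 1 else leaves[cut]
    return _combine("OR", [left, right])


def make_model(spec: ToyModelSpec, sbml_path: str | Path | None = None) -> MetabolicModel:
    """Generate a random toy :class:`MetabolicModel`.

    The first ``n_species - 1`` (at most) reactions form a chain
    s1 -> s2 -> ... over the shuffled non-recurrent species, so the
    metabolite graph is weakly connected; remaining reactions pick
    random reactant/product sets and may also involve currency species.
    When ``sbml_path`` is given the model is also serialised there.
    """
    rng = np.random.default_rng(spec.seed)
    n_recurrent = round(spec.recurrent_fraction * spec.n_species)
    n_main = spec.n_species - n_recurrent

    species: dict[str, SpeciesRecord] = {}
    main_ids = [f"M_met{i + 1:03d}_c" for i in range(n_main)]
    for i, sid in enumerate(main_ids):
        species[sid] = SpeciesRecord(sid, f"met{i + 1:03d}", "c")
    currency_ids = []
    for i in range(n_recurrent):
        name = _CURRENCY_NAMES[i % len(_CURRENCY_NAMES)]
        sid = f"M_cur{i + 1:02d}_c"
        species[sid] = SpeciesRecord(sid, name, "c")
        currency_ids.append(sid)

    pool = _gene_pool(spec.gpr_gene_pool)
    chain = [main_ids[i] for i in rng.permutation(n_main)]
    reactions: dict[str, ReactionRecord] = {}
    for k in range(spec.n_reactions):
        rid = f"R{k + 1:03d}"
        if k < n_main - 1:
            reactant_ids = [chain[k]]
            product_ids = [chain[k + 1]]
        else:
            n_r = int(rng.integers(1, 3))
            n_p = int(rng.integers(1, 3))
            picked = rng.choice(n_main, size=min(n_r + n_p, n_main), replace=False)
            reactant_ids = [main_ids[i] for i in picked[:n_r]]
            product_ids = [main_ids[i] for i in picked[n_r:]]
            if not product_ids:  # tiny models: reuse a reactant side species
                product_ids = [main_ids[int(rng.integers(0, n_main))]]
        if currency_ids and rng.random() < 0.5:
            reactant_ids = reactant_ids + [
                currency_ids[int(rng.integers(0, len(currency_ids)))]
            ]
        if currency_ids and rng.random() < 0.5:
            product_ids = product_ids + [
                currency_ids[int(rng.integers(0, len(currency_ids)))]
            ]
        gpr = (
            _random_gpr(rng, pool, spec.max_genes_per_reaction)
            if rng.random() < spec.gpr_probability
            else None
        )
        reactions[rid] = ReactionRecord(
            reaction_id=rid,
            reversible=bool(rng.random() < spec.reversible_fraction),
            reactants=tuple((s, 1.0) for s in dict.fromkeys(reactant_ids)),
            products=tuple((s, 1.0) for s in dict.fromkeys(product_ids)),
            gpr=gpr,
        )

    model = MetabolicModel(
        model_id=f"toy_{spec.seed}", species=species, reactions=reactions
    )
    if sbml_path is not None:
        write_sbml(model, sbml_path)
    return model


# ---------------------------------------------------------------------------
# SBML serialisation
# ---------------------------------------------------------------------------


def _tree_to_association(parent, tree: GPRTree) -> None:
    if tree.node_kind == "GENE":
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(f"G_{tree.gene_id}")
        return
    node = parent.createAnd() if tree.node_kind == "AND" else parent.createOr()
    for child in tree.children:
        _tree_to_association(node, child)


def model_to_sbml(model: MetabolicModel) -> str:
    """Serialise a model to an SBML Level 3 + fbc v2 document string.

    Output is fully deterministic (no timestamps; elements in model
    order) and parses back via :func:`metnet.model_io.parse_model` to a
    structurally identical model.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.model_id)
    plugin = sbml_model.getPlugin("fbc")
    plugin.setStrict(False)

    for comp_id in sorted({s.compartment for s in model.species.values()}):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for lim, value in (("lb", -1000.0), ("ub", 1000.0)):
        par = sbml_model.createParameter()
        par.setId(lim)
        par.setValue(value)
        par.setConstant(True)

    genes: set[str] = set()
    for rxn in model.reactions.values():
        if rxn.gpr is not None:
            genes.update(rxn.gpr.genes())
    for gene_id in sorted(genes):
        gp = plugin.createGeneProduct()
        gp.setId(f"G_{gene_id}")
        gp.setLabel(gene_id)

    for sid, record in model.species.items():
        sp = sbml_model.createSpecies()
        sp.setId(sid)
        sp.setName(record.name)
        sp.setCompartment(record.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(record.is_boundary)
        sp.setConstant(False)

    for rid, rxn in model.reactions.items():
        r = sbml_model.createReaction()
        r.setId(rid)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound("lb")
        rplug.setUpperFluxBound("ub")
        for sid, stoich in rxn.reactants:
            ref = r.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(stoich)
            ref.setConstant(True)
        for sid, stoich in rxn.products:
            ref = r.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(stoich)
            ref.setConstant(True)
        if rxn.gpr is not None:
            gpa = rplug.createGeneProductAssociation()
            _tree_to_association(gpa, rxn.gpr)

    return libsbml.writeSBMLToString(doc)


def write_sbml(model: MetabolicModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(model_to_sbml(model), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# classed expression populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassedPopulationSpec:
    """Parameters of a labelled expression cohort over one toy model.

    ``weight_shift`` is the additive class effect (log-expression units)
    applied to each class's disjoint signature-gene subset; with
    ``weight_shift = 0`` the classes are statistically identical and any
    downstream classifier should perform at chance.
    """

    model: ToyModelSpec = field(default_factory=ToyModelSpec)
    n_classes: int = 2
    n_samples_per_class: int = 50
    weight_shift: float = 1.0
    noise_sd: float = 0.3
    signature_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_samples_per_class <= 0:
            raise ValueError("n_samples_per_class must be positive")
        if self.weight_shift < 0:
            raise ValueError("weight_shift must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.signature_fraction <= 1:
            raise ValueError("signature_fraction must lie in (0, 1]")


@dataclass
class ClassedPopulation:
    """A toy model plus a labelled expression cohort over its genes."""

    model: MetabolicModel
    expression: ExpressionTable
    labels: LabeledCollection
    signature_genes: dict[str, tuple[str, ...]]  # class -> genes


def make_population(spec: ClassedPopulationSpec) -> ClassedPopulation:
    """Generate a labelled expression cohort over a toy model.

    Per gene g: baseline_g ~ lognormal(mu=1, sigma=0.5) (emulating the
    scale of log-FPKM values). Per sample s of class c:
    x_{g,s} = baseline_g + weight_shift * [g in signature(c)]
    + N(0, noise_sd), clipped at 0. Signature-gene subsets are disjoint
    across classes.
    """
    model = make_model(spec.model)
    rng = np.random.default_rng(spec.seed)

    genes: set[str] = set()
    for rxn in model.reactions.values():
        if rxn.gpr is not None:
            genes.update(rxn.gpr.genes())
    gene_list = sorted(genes)
    if not gene_list:
        raise ValueError("toy model has no GPR genes; cannot build a cohort")

    per_class = max(1, int(len(gene_list) * spec.signature_fraction / spec.n_classes))
    if per_class * spec.n_classes > len(gene_list):
        raise ValueError("not enough genes for disjoint class signatures")
    shuffled = [gene_list[i] for i in rng.permutation(len(gene_list))]
    class_names = [f"class{c + 1}" for c in range(spec.n_classes)]
    signatures = {
        cname: tuple(sorted(shuffled[c * per_class : (c + 1) * per_class]))
        for c, cname in enumerate(class_names)
    }

    baseline = rng.lognormal(mean=1.0, sigma=0.5, size=len(gene_list))
    columns: dict[str, np.ndarray] = {}
    sample_ids: list[str] = []
    labels: list[str] = []
    for cname in class_names:
        sig = set(signatures[cname])
        shift = np.array(
            [spec.weight_shift if g in sig else 0.0 for g in gene_list]
        )
        for j in range(spec.n_samples_per_class):
            sid = f"{cname}_s{j + 1:03d}"
            noise = rng.normal(0.0, spec.noise_sd, size=len(gene_list))
            columns[sid] = np.clip(baseline + shift + noise, 0.0, None)
            sample_ids.append(sid)
            labels.append(cname)

    frame = pd.DataFrame(columns, index=gene_list)
    return ClassedPopulation(
        model=model,
        expression=ExpressionTable(frame),
        labels=LabeledCollection(tuple(sample_ids), tuple(labels)),
        signature_genes=signatures,
    )
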