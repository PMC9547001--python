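"""Readers for genome-scale metabolic models and their companion inputs.

This module turns the on-disk inputs of a metabolic-graph workflow into
plain Python objects:

* SBML model files (Level 3 with ``fbc`` gene-product associations, or
  older files carrying ``GENE_ASSOCIATION`` strings in reaction notes)
  become :class:`MetabolicModel` instances;
* boolean gene-protein-reaction (GPR) rules become :class:`GPRTree`
  expressions, convertible to disjunctive normal form as lists of
  :class:`EnzymeComplex`;
* tab-separated expression tables (genes x samples, e.g. log-FPKM)
  become :class:`ExpressionTable`;
* plain-text currency-metabolite lists become :class:`RecurrentSet`.

Flux bounds, objectives and other constraint-based-modelling attributes
are deliberately ignored: graph construction needs only stoichiometric
membership, reversibility and gene associations.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import libsbml
import numpy as np
import pandas as pd

from .exceptions import (
    ExpressionParseError,
    GPRParseError,
    InvalidModelError,
    ModelValidationWarning,
)

__all__ = [
    "SpeciesRecord",
    "GPRTree",
    "EnzymeComplex",
    "ReactionRecord",
    "MetabolicModel",
    "ExpressionTable",
    "RecurrentSet",
    "DEFAULT_RECURRENT_NAMES",
    "parse_model",
    "parse_gpr",
    "render_gpr",
    "gpr_to_dnf",
    "load_expression",
    "load_recurrent_set",
]

ENSEMBL_ID_RE = re.compile(r"^ENS[A-Z]*[0-9]{11}$")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesRecord:
    """One SBML species: a metabolite in a specific compartment."""

    species_id: str
    name: str
    compartment: str
    is_boundary: bool = False

    def base_names(self) -> tuple[str, ...]:
        """Compartment-free, lower-cased identifiers used for recurrent
        matching: the display name plus the species id with common
        prefix (``M_``/``m_``) and compartment suffix stripped."""
        candidates = set()
        if self.name:
            candidates.add(self.name.strip().lower())
        sid = self.species_id
        stripped = re.sub(r"^[Mm]_", "", sid)
        comp = re.escape(self.compartment)
        stripped = re.sub(rf"(_{comp}|\[{comp}\])$", "", stripped)
        candidates.add(stripped.lower())
        return tuple(sorted(candidates))


@dataclass(frozen=True)
class GPRTree:
    """Boolean gene-association expression.

    ``node_kind`` is ``"GENE"`` (leaf, with ``gene_id`` set) or one of the
    operators ``"AND"`` / ``"OR"`` (with ``children``, at least two).
    Trees are kept canonical: nested nodes with the same operator are
    flattened and single-child operators collapsed.
    """

    node_kind: str
    gene_id: str | None = None
    children: tuple["GPRTree", ...] = ()

    def __post_init__(self) -> None:
        if self.node_kind == "GENE":
            if not self.gene_id or self.children:
                raise ValueError("GENE node needs gene_id and no children")
        elif self.node_kind in ("AND", "OR"):
            if len(self.children) < 2:
                raise ValueError(f"{self.node_kind} node needs >= 2 children")
        else:
            raise ValueError(f"unknown node kind {self.node_kind!r}")

    def genes(self) -> tuple[str, ...]:
        """All gene ids in the tree, deduplicated, sorted."""
        if self.node_kind == "GENE":
            return (self.gene_id,)
        seen: set[str] = set()
        for child in self.children:
            seen.update(child.genes())
        return tuple(sorted(seen))

    def evaluate(self, active: Iterable[str]) -> bool:
        """Truth value under a set of active genes."""
        active = set(active)
        if self.node_kind == "GENE":
            return self.gene_id in active
        if self.node_kind == "AND":
            return all(c.evaluate(active) for c in self.children)
        return any(c.evaluate(active) for c in self.children)


def _gene(gene_id: str) -> GPRTree:
    return GPRTree("GENE", gene_id=gene_id)


def _combine(kind: str, parts: Sequence[GPRTree]) -> GPRTree:
    """Build an AND/OR node, flattening nested same-operator children."""
    if len(parts) == 1:
        return parts[0]
    flat: list[GPRTree] = []
    for p in parts:
        if p.node_kind == kind:
            flat.extend(p.children)
        else:
            flat.append(p)
    return GPRTree(kind, children=tuple(flat))


@dataclass(frozen=True, order=True)
class EnzymeComplex:
    """A set of genes jointly required to catalyse a reaction (one
    AND-conjunct of a GPR in disjunctive normal form)."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("enzyme complex must contain >= 1 gene")
        object.__setattr__(self, "genes", tuple(sorted(set(self.genes))))

    @property
    def label(self) -> str:
        """Canonical node label: sorted genes joined with ``_AND_``."""
        return "_AND_".join(self.genes)


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: reactant/product membership, reversibility, GPR.

    A species may legally appear on both sides; it is then present in
    both ``reactants`` and ``products``. Stoichiometries are recorded but
    not used by any graph builder.
    """

    reaction_id: str
    reversible: bool
    reactants: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    gpr: GPRTree | None = None

    def __post_init__(self) -> None:
        for side in (self.reactants, self.products):
            for sid, stoich in side:
                if not stoich > 0:
                    raise ValueError(
                        f"reaction {self.reaction_id}: stoichiometry of "
                        f"{sid} must be > 0, got {stoich}"
                    )

    @property
    def reactant_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.reactants)

    @property
    def product_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.products)


@dataclass
class MetabolicModel:
    """A parsed metabolic model: species and reactions by id."""

    model_id: str
    species: dict[str, SpeciesRecord]
    reactions: dict[str, ReactionRecord]

    def __post_init__(self) -> None:
        if not self.reactions:
            raise InvalidModelError(f"model {self.model_id!r} has no reactions")
        for rxn in self.reactions.values():
            for sid in rxn.reactant_ids + rxn.product_ids:
                if sid not in self.species:
                    raise InvalidModelError(
                        f"reaction {rxn.reaction_id} references unknown "
                        f"species {sid}"
                    )


class ExpressionTable:
    """Gene-by-sample expression matrix (typically log-transformed FPKM).

    Thin wrapper over a pandas DataFrame (genes on the index, samples on
    the columns) that enforces uniqueness, finiteness and non-negativity.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression table")
        if frame.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression table")
        values = frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression table contains non-finite values")
        if (values < 0).any():
            raise ValueError("expression table contains negative values")
        self._frame = frame.astype(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def genes(self) -> list[str]:
        return list(self._frame.index)

    @property
    def samples(self) -> list[str]:
        return list(self._frame.columns)

    def value(self, gene_id: str, sample_id: str) -> float | None:
        """Expression of one gene in one sample; None when the gene is
        not measured."""
        if gene_id not in self._frame.index:
            return None
        return float(self._frame.at[gene_id, sample_id])

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._frame.index


#: Currency metabolites excluded by default from graph construction:
#: ubiquitous small molecules and cofactors whose shared participation in
#: thousands of reactions would create biologically meaningless shortcut
#: paths. User lists loaded with :func:`load_recurrent_set` replace this.
DEFAULT_RECURRENT_NAMES: frozenset[str] = frozenset(
    {
        "h2o", "water",
        "h+", "h", "proton",
        "atp", "adp", "amp",
        "gtp", "gdp", "gmp",
        "utp", "udp", "ump",
        "ctp", "cdp", "cmp",
        "co2", "hco3-",
        "nh3", "nh4+",
        "o2", "h2o2",
        "pi", "phosphate", "ppi", "diphosphate", "pyrophosphate",
        "nad+", "nad", "nadh",
        "nadp+", "nadp", "nadph",
        "fad", "fadh2",
        "coa", "coenzyme a", "acetyl-coa",
        "so4", "sulfate",
    }
)


class RecurrentSet:
    """Compartment-free names of recurrent (currency) metabolites.

    Membership of a species is tested against its display name and its
    compartment-stripped id, case-insensitively.
    """

    def __init__(self, names: Iterable[str]):
        cleaned = {n.strip().lower() for n in names if n.strip()}
        if not cleaned:
            raise ValueError("recurrent-metabolite set must be non-empty")
        self.names: frozenset[str] = frozenset(cleaned)

    @classmethod
    def default(cls) -> "RecurrentSet":
        return cls(DEFAULT_RECURRENT_NAMES)

    def matches(self, species: SpeciesRecord) -> bool:
        return any(base in self.names for base in species.base_names())

    def __contains__(self, name: str) -> bool:
        return name.strip().lower() in self.names

    def __len__(self) -> int:
        return len(self.names)

    def __or__(self, other: "RecurrentSet") -> "RecurrentSet":
        return RecurrentSet(self.names | other.names)


# ---------------------------------------------------------------------------
# GPR parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: str) -> GPRTree:
    """Parse a boolean gene-association rule into a canonical tree.

    Grammar (``and`` binds tighter than ``or``; both case-insensitive)::

        expr   := term  ( "or"  term  )*
        term   := factor( "and" factor)*
        factor := "(" expr ")" | GENE_ID

    Nested same-operator nodes are flattened, so ``a and b and c`` is a
    single three-child AND node.
    """
    tokens = _TOKEN_RE.findall(rule)
    if not tokens:
        raise GPRParseError("empty GPR rule")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr() -> GPRTree:
        parts = [parse_term()]
        while peek() is not None and peek().lower() == "or":
            advance()
            parts.append(parse_term())
        return _combine("OR", parts)

    def parse_term() -> GPRTree:
        parts = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            advance()
            parts.append(parse_factor())
        return _combine("AND", parts)

    def parse_factor() -> GPRTree:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of rule: {rule!r}")
        if tok == "(":
            advance()
            inner = parse_expr()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in {rule!r}")
            advance()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"dangling operator or parenthesis in {rule!r}")
        return _gene(advance())

    tree = parse_expr()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in {rule!r}")
    return tree


def render_gpr(tree: GPRTree) -> str:
    """Render a GPRTree back to rule syntax (inverse of :func:`parse_gpr`
    on canonical trees)."""
    if tree.node_kind == "GENE":
        return tree.gene_id
    op = " and " if tree.node_kind == "AND" else " or "
    parts = []
    for child in tree.children:
        text = render_gpr(child)
        if tree.node_kind == "AND" and child.node_kind == "OR":
            text = f"({text})"
        parts.append(text)
    return op.join(parts)


def gpr_to_dnf(tree: GPRTree) -> list[EnzymeComplex]:
    """Disjunctive normal form of a GPR: the alternative enzyme complexes.

    Each returned :class:`EnzymeComplex` is one AND-conjunct (genes that
    must all be present); the reaction can be catalysed by any one of
    them. The list is deduplicated, absorption-reduced (a complex that is
    a strict superset of another is dropped) and sorted.
    """
    if tree.node_kind == "GENE":
        conjuncts = [frozenset([tree.gene_id])]
    elif tree.node_kind == "OR":
        seen: set[frozenset[str]] = set()
        conjuncts = []
        for child in tree.children:
            for cpx in gpr_to_dnf(child):
                fs = frozenset(cpx.genes)
                if fs not in seen:
                    seen.add(fs)
                    conjuncts.append(fs)
    else:  # AND: distribute over the children's DNFs
        partial: list[frozenset[str]] = [frozenset()]
        for child in tree.children:
            child_dnf = [frozenset(c.genes) for c in gpr_to_dnf(child)]
            partial = [p | c for p in partial for c in child_dnf]
        conjuncts = list(dict.fromkeys(partial))
    # absorption: drop any conjunct strictly containing another
    kept = [
        c
        for c in conjuncts
        if not any(other < c for other in conjuncts)
    ]
    return sorted(EnzymeComplex(tuple(c)) for c in set(kept))


# ---------------------------------------------------------------------------
# SBML parsing
# ---------------------------------------------------------------------------

_NOTES_GPR_RE = re.compile(
    r"GENE[ _]?ASSOCIATION\s*:\s*([^<\n]*)", re.IGNORECASE
)


def _association_to_tree(
    assoc: "libsbml.FbcAssociation", gene_labels: Mapping[str, str]
) -> GPRTree:
    if assoc.isGeneProductRef():
        gp_id = assoc.getGeneProduct()
        return _gene(gene_labels.get(gp_id, gp_id))
    kind = "AND" if assoc.isFbcAnd() else "OR"
    children = [
        _association_to_tree(assoc.getAssociation(i), gene_labels)
        for i in range(assoc.getNumAssociations())
    ]
    return _combine(kind, children)


def _read_fbc_gpr(
    reaction: "libsbml.Reaction", gene_labels: Mapping[str, str]
) -> GPRTree | None:
    plugin = reaction.getPlugin("fbc")
    if plugin is None:
        return None
    gpa = plugin.getGeneProductAssociation()
    if gpa is None or gpa.getAssociation() is None:
        return None
    return _association_to_tree(gpa.getAssociation(), gene_labels)


def _read_notes_gpr(reaction: "libsbml.Reaction") -> GPRTree | None:
    if not reaction.isSetNotes():
        return None
    match = _NOTES_GPR_RE.search(reaction.getNotesString())
    if match is None:
        return None
    rule = match.group(1).strip()
    if not rule or rule in ("-", "NA", "None"):
        return None
    return parse_gpr(rule)


def parse_model(path: str | Path, dialect: str = "auto") -> MetabolicModel:
    """Read an SBML file into a :class:`MetabolicModel`.

    Parameters
    ----------
    path:
        SBML file (Level 2 or 3; ``.xml`` or ``.xml.gz``).
    dialect:
        Where gene associations live: ``"fbc"`` (fbc package
        ``geneProductAssociation``), ``"notes"`` (``GENE_ASSOCIATION``
        strings in reaction notes), or ``"auto"`` (per reaction, fbc
        preferred with notes as fallback).

    Lightweight validation is performed while reading: reactions missing
    flux bounds or with unparsable GPRs produce
    :class:`~metnet.exceptions.ModelValidationWarning`; a reaction with
    neither reactants nor products, a model with zero reactions, or
    malformed XML raise :class:`~metnet.exceptions.InvalidModelError`.
    """
    if dialect not in ("auto", "fbc", "notes"):
        raise ValueError(f"unknown GPR dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBML(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise InvalidModelError(
                f"SBML parse error in {path.name}: {err.getMessage().strip()}"
            )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise InvalidModelError(f"{path.name}: no <model> element")

    model_id = sbml_model.getId() or path.stem

    # fbc gene product id -> Ensembl label
    gene_labels: dict[str, str] = {}
    model_plugin = sbml_model.getPlugin("fbc")
    if model_plugin is not None:
        for i in range(model_plugin.getNumGeneProducts()):
            gp = model_plugin.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    species: dict[str, SpeciesRecord] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        compartment = sp.getCompartment()
        if not compartment:
            warnings.warn(
                f"species {sp.getId()} has no compartment",
                ModelValidationWarning,
                stacklevel=2,
            )
            compartment = "default"
        species[sp.getId()] = SpeciesRecord(
            species_id=sp.getId(),
            name=sp.getName() or sp.getId(),
            compartment=compartment,
            is_boundary=bool(sp.getBoundaryCondition()),
        )

    reactions: dict[str, ReactionRecord] = {}
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        rid = rxn.getId()
        if not rid:
            raise InvalidModelError(f"{path.name}: reaction #{i} has no id")
        reactants = tuple(
            (rxn.getReactant(j).getSpecies(), float(rxn.getReactant(j).getStoichiometry()))
            for j in range(rxn.getNumReactants())
        )
        products = tuple(
            (rxn.getProduct(j).getSpecies(), float(rxn.getProduct(j).getStoichiometry()))
            for j in range(rxn.getNumProducts())
        )
        if not reactants and not products:
            raise InvalidModelError(
                f"reaction {rid} has neither reactants nor products"
            )
        plugin = rxn.getPlugin("fbc")
        if plugin is not None and not (
            plugin.isSetLowerFluxBound() and plugin.isSetUpperFluxBound()
        ):
            warnings.warn(
                f"reaction {rid} is missing flux bounds (ignored by graph "
                "construction)",
                ModelValidationWarning,
                stacklevel=2,
            )
        gpr: GPRTree | None = None
        try:
            if dialect in ("auto", "fbc"):
                gpr = _read_fbc_gpr(rxn, gene_labels)
            if gpr is None and dialect in ("auto", "notes"):
                gpr = _read_notes_gpr(rxn)
        except GPRParseError as exc:
            warnings.warn(
                f"reaction {rid}: unparsable GPR ({exc}); treated as absent",
                ModelValidationWarning,
                stacklevel=2,
            )
            gpr = None
        if gpr is not None:
            for gene_id in gpr.genes():
                if not ENSEMBL_ID_RE.match(gene_id):
                    warnings.warn(
                        f"reaction {rid}: gene id {gene_id!r} does not look "
                        "like an Ensembl stable ID",
                        ModelValidationWarning,
                        stacklevel=2,
                    )
                    break
        reactions[rid] = ReactionRecord(
            reaction_id=rid,
            reversible=bool(rxn.getReversible()),
            reactants=reactants,
            products=products,
            gpr=gpr,
        )

    return MetabolicModel(model_id=model_id, species=species, reactions=reactions)


# ---------------------------------------------------------------------------
# expression tables and recurrent lists
# ---------------------------------------------------------------------------


def load_expression(path: str | Path) -> ExpressionTable:
    """Load a tab-separated expression table (first column gene ids,
    header row sample ids).

    Duplicate gene rows are collapsed by their mean with a warning;
    any cell that does not parse as a finite number is an error.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    for col in frame.columns:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() | ~np.isfinite(values)
        if bad.any():
            gene = frame.index[bad.to_numpy()][0]
            raise ExpressionParseError(
                f"{path.name}: non-numeric value for gene {gene!r} in "
                f"sample {col!r}"
            )
        frame[col] = values
    if frame.index.has_duplicates:
        dupes = sorted(set(frame.index[frame.index.duplicated()]))
        warnings.warn(
            f"{path.name}: duplicate gene rows collapsed by mean: "
            f"{', '.join(dupes[:5])}",
            ModelValidationWarning,
            stacklevel=2,
        )
        frame = frame.groupby(level=0, sort=False).mean()
    return ExpressionTable(frame)


def load_recurrent_set(path: str | Path | None = None) -> RecurrentSet:
    """Load a recurrent-metabolite list (one base-name per line, blanks
    ignored); with no path, return the built-in default list."""
    if path is None:
        return RecurrentSet.default()
    lines = Path(path).read_text().splitlines()
    names = [ln.strip() for ln in lines if ln.strip()]
    if not names:
        raise ValueError(f"recurrent-metabolite file {path} is empty")
    return RecurrentSet(names)
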