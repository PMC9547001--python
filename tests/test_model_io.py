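"""Unit tests for SBML/GPR/expression parsing."""

from __future__ import annotations

import textwrap

import pytest
from hypothesis import given
from hypothesis import strategies as st

from metnet.exceptions import (
    ExpressionParseError,
    GPRParseError,
    InvalidModelError,
    ModelValidationWarning,
)
from metnet.model_io import (
    EnzymeComplex,
    ExpressionTable,
    GPRTree,
    RecurrentSet,
    SpeciesRecord,
    gpr_to_dnf,
    load_expression,
    load_recurrent_set,
    parse_gpr,
    parse_model,
    render_gpr,
)

# ---------------------------------------------------------------------------
# GPR parsing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "rule, kind, arity",
    [
        ("g1 and g2 and g3", "AND", 3),  # same-operator flattening
        ("g1 or g2 or g3 or g4", "OR", 4),
        ("((g1))", "GENE", 0),  # parenthesis elision
        ("g1", "GENE", 0),
    ],
)
def test_parse_gpr_shapes(rule, kind, arity):
    tree = parse_gpr(rule)
    assert tree.node_kind == kind
    assert len(tree.children) == arity


def test_parse_gpr_precedence():
    """'and' binds tighter than 'or'."""
    tree = parse_gpr("g1 or g2 and g3")
    assert tree.node_kind == "OR"
    assert tree.children[0] == GPRTree("GENE", gene_id="g1")
    assert tree.children[1].node_kind == "AND"
    assert [c.gene_id for c in tree.children[1].children] == ["g2", "g3"]


def test_parse_gpr_parentheses_override_precedence():
    tree = parse_gpr("(g1 or g2) and g3")
    assert tree.node_kind == "AND"
    assert tree.children[0].node_kind == "OR"


@pytest.mark.parametrize(
    "rule", ["", "g1 and", "(g1 or g2", "g1 ) g2", "and g1", "g1 or or g2", "g1 g2"]
)
def test_parse_gpr_rejects_malformed(rule):
    with pytest.raises(GPRParseError):
        parse_gpr(rule)


_genes = st.sampled_from([f"g{i}" for i in range(1, 7)])


def _trees(max_genes=6):
    return st.recursive(
        _genes.map(lambda g: GPRTree("GENE", gene_id=g)),
        lambda children: st.tuples(
            st.sampled_from(["AND", "OR"]),
            st.lists(children, min_size=2, max_size=3),
        ).map(lambda t: _canonical(t[0], t[1])),
        max_leaves=6,
    )


def _canonical(kind, parts):
    flat = []
    for p in parts:
        if p.node_kind == kind:
            flat.extend(p.children)
        else:
            flat.append(p)
    return GPRTree(kind, children=tuple(flat)) if len(flat) > 1 else flat[0]


@given(_trees())
def test_render_parse_round_trip(tree):
    """parse_gpr(render_gpr(t)) reproduces every canonical tree."""
    assert parse_gpr(render_gpr(tree)) == tree


# ---------------------------------------------------------------------------
# DNF conversion
# ---------------------------------------------------------------------------


def _dnf_satisfied(complexes, active):
    return any(set(c.genes) <= set(active) for c in complexes)


def _all_subsets(genes):
    from itertools import combinations

    for k in range(len(genes) + 1):
        yield from combinations(genes, k)


@pytest.mark.parametrize(
    "rule, expected",
    [
        ("(g1 and g2) or g3", [("g1", "g2"), ("g3",)]),
        ("(g1 or g2) and g3", [("g1", "g3"), ("g2", "g3")]),
        ("g1", [("g1",)]),
        ("g1 or (g1 and g2)", [("g1",)]),  # absorption removes the superset
        ("g1 or g1", [("g1",)]),  # deduplication
    ],
)
def test_gpr_to_dnf_examples(rule, expected):
    assert [c.genes for c in gpr_to_dnf(parse_gpr(rule))] == expected


@given(_trees())
def test_dnf_truth_table_equivalence(tree):
    """The DNF satisfies exactly the same gene assignments as the tree,
    exhaustively over all subsets of its (<= 6) genes."""
    complexes = gpr_to_dnf(tree)
    genes = tree.genes()
    for active in _all_subsets(genes):
        assert _dnf_satisfied(complexes, active) == tree.evaluate(active)


def test_enzyme_complex_canonical_form():
    assert EnzymeComplex(("b", "a", "b")).genes == ("a", "b")
    assert EnzymeComplex(("a", "b")).label == "a_AND_b"
    assert EnzymeComplex(("b", "a")) == EnzymeComplex(("a", "b"))
    with pytest.raises(ValueError):
        EnzymeComplex(())


# ---------------------------------------------------------------------------
# SBML parsing
# ---------------------------------------------------------------------------

_FBC_SBML = textwrap.dedent(
    """\
    <?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
          xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
          level="3" version="1" fbc:required="false">
      <model id="toy3" fbc:strict="false">
        <listOfCompartments>
          <compartment id="c" constant="true"/>
        </listOfCompartments>
        <listOfSpecies>
          <species id="M_a_c" name="alpha" compartment="c" constant="false"
                   boundaryCondition="false" hasOnlySubstanceUnits="false"/>
          <species id="M_b_c" name="beta" compartment="c" constant="false"
                   boundaryCondition="false" hasOnlySubstanceUnits="false"/>
          <species id="M_c_c" name="gamma" compartment="c" constant="false"
                   boundaryCondition="false" hasOnlySubstanceUnits="false"/>
          <species id="M_d_c" name="delta" compartment="c" constant="false"
                   boundaryCondition="false" hasOnlySubstanceUnits="false"/>
        </listOfSpecies>
        <fbc:listOfGeneProducts>
          <fbc:geneProduct fbc:id="G_ENSG00000000001" fbc:label="ENSG00000000001"/>
          <fbc:geneProduct fbc:id="G_ENSG00000000002" fbc:label="ENSG00000000002"/>
          <fbc:geneProduct fbc:id="G_ENSG00000000003" fbc:label="ENSG00000000003"/>
        </fbc:listOfGeneProducts>
        <listOfReactions>
          <reaction id="R1" reversible="false" fast="false">
            <listOfReactants>
              <speciesReference species="M_a_c" stoichiometry="1" constant="true"/>
            </listOfReactants>
            <listOfProducts>
              <speciesReference species="M_b_c" stoichiometry="1" constant="true"/>
            </listOfProducts>
            <fbc:geneProductAssociation>
              <fbc:or>
                <fbc:and>
                  <fbc:geneProductRef fbc:geneProduct="G_ENSG00000000001"/>
                  <fbc:geneProductRef fbc:geneProduct="G_ENSG00000000002"/>
                </fbc:and>
                <fbc:geneProductRef fbc:geneProduct="G_ENSG00000000003"/>
              </fbc:or>
            </fbc:geneProductAssociation>
          </reaction>
          <reaction id="R2" reversible="true" fast="false">
            <listOfReactants>
              <speciesReference species="M_b_c" stoichiometry="1" constant="true"/>
            </listOfReactants>
            <listOfProducts>
              <speciesReference species="M_c_c" stoichiometry="2" constant="true"/>
            </listOfProducts>
          </reaction>
          <reaction id="R3" reversible="false" fast="false">
            <listOfReactants>
              <speciesReference species="M_c_c" stoichiometry="1" constant="true"/>
            </listOfReactants>
            <listOfProducts>
              <speciesReference species="M_d_c" stoichiometry="1" constant="true"/>
            </listOfProducts>
          </reaction>
        </listOfReactions>
      </model>
    </sbml>
    """
)

_NOTES_SBML = textwrap.dedent(
    """\
    <?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
      <model id="legacy">
        <listOfCompartments>
          <compartment id="c"/>
        </listOfCompartments>
        <listOfSpecies>
          <species id="M_a_c" name="alpha" compartment="c"/>
          <species id="M_b_c" name="beta" compartment="c"/>
        </listOfSpecies>
        <listOfReactions>
          <reaction id="R1" reversible="false">
            <notes>
              <body xmlns="http://www.w3.org/1999/xhtml">
                <p>GENE_ASSOCIATION: ENSG00000000007 and ENSG00000000008</p>
              </body>
            </notes>
            <listOfReactants>
              <speciesReference species="M_a_c"/>
            </listOfReactants>
            <listOfProducts>
              <speciesReference species="M_b_c"/>
            </listOfProducts>
          </reaction>
        </listOfReactions>
      </model>
    </sbml>
    """
)


@pytest.fixture
def fbc_file(tmp_path):
    path = tmp_path / "toy.xml"
    path.write_text(_FBC_SBML)
    return path


def test_parse_model_fbc_fixture(fbc_file):
    """The 3-reaction fixture parses completely: species, reversibility,
    stoichiometry and the fbc gene association."""
    with pytest.warns(ModelValidationWarning):  # fixture lacks flux bounds
        model = parse_model(fbc_file)
    assert len(model.reactions) == 3
    assert len(model.species) == 4
    assert model.reactions["R2"].reversible
    assert model.reactions["R2"].products == (("M_c_c", 2.0),)
    gpr = model.reactions["R1"].gpr
    assert gpr.node_kind == "OR"
    assert gpr == parse_gpr(
        "(ENSG00000000001 and ENSG00000000002) or ENSG00000000003"
    )
    assert model.reactions["R2"].gpr is None


def test_parse_model_notes_dialect(tmp_path):
    path = tmp_path / "legacy.xml"
    path.write_text(_NOTES_SBML)
    model = parse_model(path, dialect="notes")
    gpr = model.reactions["R1"].gpr
    assert gpr is not None and gpr.node_kind == "AND"
    assert gpr.genes() == ("ENSG00000000007", "ENSG00000000008")
    # auto-detection falls back to notes when no fbc association exists
    assert parse_model(path).reactions["R1"].gpr == gpr


def test_parse_model_is_deterministic(fbc_file):
    with pytest.warns(ModelValidationWarning):
        first = parse_model(fbc_file)
    with pytest.warns(ModelValidationWarning):
        second = parse_model(fbc_file)
    assert first.species == second.species
    assert first.reactions == second.reactions


def test_parse_model_empty_reaction_is_error(tmp_path):
    import re

    bad = re.sub(
        r'<reaction id="R3".*?</reaction>',
        '<reaction id="R3" reversible="false" fast="false"/>',
        _FBC_SBML,
        flags=re.DOTALL,
    )
    assert "M_d_c" in bad.split("listOfReactions")[0]  # species list untouched
    path = tmp_path / "bad.xml"
    path.write_text(bad)
    with pytest.raises(InvalidModelError, match="neither reactants nor products"):
        parse_model(path)


def test_parse_model_malformed_xml(tmp_path):
    path = tmp_path / "broken.xml"
    path.write_text("<sbml><model>")
    with pytest.raises(InvalidModelError):
        parse_model(path)


def test_parse_model_zero_reactions(tmp_path):
    doc = _NOTES_SBML.split("<listOfReactions>")[0] + "</model>\n</sbml>\n"
    path = tmp_path / "empty.xml"
    path.write_text(doc)
    with pytest.raises(InvalidModelError, match="no reactions"):
        parse_model(path)


def test_unparsable_gpr_becomes_warning(tmp_path):
    doc = _NOTES_SBML.replace(
        "ENSG00000000007 and ENSG00000000008", "ENSG00000000007 and ("
    )
    path = tmp_path / "badgpr.xml"
    path.write_text(doc)
    with pytest.warns(ModelValidationWarning, match="unparsable GPR"):
        model = parse_model(path, dialect="notes")
    assert model.reactions["R1"].gpr is None


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def test_load_expression_round_trip(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text("gene\ts1\ts2\ts3\ng1\t1.5\t2\t0\ng2\t4\t5.5\t6\n")
    table = load_expression(path)
    assert table.genes == ["g1", "g2"]
    assert table.samples == ["s1", "s2", "s3"]
    assert table.value("g2", "s2") == 5.5
    assert table.value("missing", "s1") is None


def test_load_expression_collapses_duplicates(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text("gene\ts1\ng1\t2\ng1\t4\n")
    with pytest.warns(ModelValidationWarning, match="duplicate gene rows"):
        table = load_expression(path)
    assert table.value("g1", "s1") == 3.0


def test_load_expression_rejects_na(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text("gene\ts1\ts2\ng1\t1\tNA\n")
    with pytest.raises(ExpressionParseError, match="g1.*s2"):
        load_expression(path)


def test_expression_table_invariants():
    import pandas as pd

    with pytest.raises(ValueError, match="negative"):
        ExpressionTable(pd.DataFrame({"s1": [-1.0]}, index=["g1"]))
    with pytest.raises(ValueError, match="non-finite"):
        ExpressionTable(pd.DataFrame({"s1": [float("nan")]}, index=["g1"]))
    with pytest.raises(ValueError, match="duplicate gene"):
        ExpressionTable(pd.DataFrame({"s1": [1.0, 2.0]}, index=["g1", "g1"]))


# ---------------------------------------------------------------------------
# recurrent sets
# ---------------------------------------------------------------------------


def test_load_recurrent_set_from_file(tmp_path):
    path = tmp_path / "rec.txt"
    path.write_text("ATP\nH2O\n\nATP\n")  # blank line and duplicate
    rec = load_recurrent_set(path)
    assert len(rec) == 2
    assert "atp" in rec and "H2O" in rec


def test_default_recurrent_set_covers_currency_metabolites():
    rec = load_recurrent_set(None)
    for name in ["H2O", "ATP", "ADP", "AMP", "CO2", "NH3", "O2", "Pi",
                 "phosphate", "H+", "NAD", "NADH", "NADP", "NADPH",
                 "FAD", "FADH2", "CoA"]:
        assert name in rec, name


def test_recurrent_empty_file_is_error(tmp_path):
    path = tmp_path / "empty.txt"
    path.write_text("\n\n")
    with pytest.raises(ValueError, match="empty"):
        load_recurrent_set(path)


def test_recurrent_matching_is_compartment_free_and_case_insensitive():
    rec = RecurrentSet(["ATP"])
    assert rec.matches(SpeciesRecord("M_atp_c", "ATP", "c"))
    assert rec.matches(SpeciesRecord("atp[m]", "adenosine triphosphate", "m"))
    assert not rec.matches(SpeciesRecord("M_glc_c", "glucose", "c"))
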