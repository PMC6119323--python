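"""Compositional-grammar parsing and serialization."""

import random
from decimal import Decimal

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sctoforge import examples as ex
from sctoforge.cg import (
    CGParseError,
    ConceptRef,
    ConcreteValue,
    parse_cg,
    serialize_cg,
    strip_terms,
)
from helpers import random_cg_ast


class TestWorkedExamples:
    @pytest.mark.parametrize("name,text", sorted(ex.ALL_EXAMPLES.items()))
    def test_parses_and_round_trips(self, name, text):
        ast = parse_cg(text)
        assert parse_cg(serialize_cg(ast, with_terms=True)) == ast

    def test_combination_normal_form_ast(self):
        ast = parse_cg(ex.NEEDLE_BIOPSY)
        assert ast.status == "equivalent"
        assert {f.sctid for f in ast.focus} == {"129249002", "7246002"}
        assert not ast.ungrouped and not ast.groups

    def test_pre_coordination_uses_subtype_status_and_juxtaposition(self):
        ast = parse_cg(ex.DIABETES)
        assert ast.status == "subtype"
        assert ast.subject == ConceptRef("73211009")
        assert [f.sctid for f in ast.focus] == ["126877002", "362969004"]
        (attr,) = ast.ungrouped
        assert attr.name.sctid == "363698007"
        assert attr.value == ConceptRef("113331007")

    def test_nested_refinement_with_concrete_value(self):
        ast = parse_cg(ex.AMOXICILLIN_CAPSULE)
        assert ast.focus == (ConceptRef("27658006"),)
        (dose,) = ast.ungrouped
        assert dose.name.sctid == "411116001" and dose.value == ConceptRef("385049006")
        (group,) = ast.groups
        assert len(group) == 2
        nested = group[1].value
        magnitude = nested.attributes()[0]
        assert magnitude.value == ConcreteValue("numeric", numeric_value=Decimal(500))
        unit = nested.attributes()[1]
        assert unit.value == ConceptRef("258684004")

    def test_parenthesized_groups_in_complex_example(self):
        ast = parse_cg(ex.CLOSED_SKULL_FRACTURE)
        assert len(ast.groups) == 2
        assert all(len(g) == 2 for g in ast.groups)
        roles = {a.name.sctid for g in ast.groups for a in g}
        assert roles == {"116676008", "363698007"}

    def test_nested_expression_value_with_own_refinement(self):
        ast = parse_cg(ex.BACTERIAL_PNEUMONIA)
        site = ast.find_attribute("363698007")
        nested = site.value
        assert nested.focus[0].sctid == "45653009"
        assert nested.find_attribute("272741003").value == ConceptRef("7771000")


class TestErrors:
    @pytest.mark.parametrize("text", ["===", "", "   ", "73211009:", "{}",
                                      "73211009 |unterminated", "1 = "])
    def test_degenerate_inputs_raise_parse_errors(self, text):
        with pytest.raises((CGParseError, ValueError)):
            parse_cg(text)

    def test_error_carries_character_offset(self):
        with pytest.raises(CGParseError) as err:
            parse_cg("129249002, ]")
        assert err.value.offset == 11

    def test_standard_dialect_requires_equals(self):
        parse_cg("125605004: 363698007 181940002", dialect="paper")
        with pytest.raises(CGParseError):
            parse_cg("125605004: 363698007 181940002", dialect="standard")


class TestProperties:
    def test_terms_never_change_parsed_semantics(self):
        for text in ex.ALL_EXAMPLES.values():
            assert parse_cg(text) == parse_cg(strip_terms(text))

    def test_round_trip_stability_on_random_asts(self):
        rng = random.Random(20150731)
        for _ in range(500):
            ast = random_cg_ast(rng)
            text = serialize_cg(ast, with_terms=False)
            reparsed = parse_cg(text)
            assert reparsed == ast
            assert parse_cg(serialize_cg(reparsed, with_terms=False)) == reparsed

    def test_dialects_agree_on_braces_style_groups(self):
        rng = random.Random(7)
        for _ in range(100):
            ast = random_cg_ast(rng)
            text = serialize_cg(ast, with_terms=False)  # canonical text uses braces
            assert parse_cg(text, dialect="paper") == parse_cg(text, dialect="standard")

    def test_plus_joins_focus_concepts_in_standard_dialect(self):
        assert (parse_cg("7246002 + 129249002", dialect="standard")
                == parse_cg("7246002, 129249002", dialect="standard"))
        with pytest.raises(CGParseError):
            parse_cg("7246002 + 129249002", dialect="paper")


_sctids = st.integers(min_value=1, max_value=10**9 - 1).map(str)
_refs = st.builds(ConceptRef, _sctids)
_concretes = st.builds(
    lambda n: ConcreteValue("numeric", numeric_value=Decimal(n)),
    st.integers(min_value=1, max_value=999))


@st.composite
def _expressions(draw, depth=1):
    from sctoforge.cg import CGAttribute, CGExpression

    value = _refs | _concretes
    if depth > 0:
        value = value | _expressions(depth=depth - 1)
    attrs = st.builds(CGAttribute, _refs, value)
    return draw(st.builds(
        CGExpression,
        status=st.sampled_from(["equivalent", "subtype"]),
        focus=st.tuples(_refs) | st.tuples(_refs, _refs),
        ungrouped=st.lists(attrs, max_size=2).map(tuple),
        groups=st.lists(st.lists(attrs, min_size=1, max_size=2).map(tuple),
                        max_size=2).map(tuple),
    ))


@settings(max_examples=150, derandomize=True, deadline=None)
@given(_expressions())
def test_serialization_round_trip_is_identity(ast):
    assert parse_cg(serialize_cg(ast, with_terms=False)) == ast


def test_single_focus_serializes_to_bare_sctid():
    assert serialize_cg(parse_cg("73211009 |Diabetes mellitus|")) == "73211009"
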