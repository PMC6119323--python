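"""SCTO builder: scaffold, mapping, reification, groups, SCM validation."""

import random

import pytest

from sctoforge import examples as ex
from sctoforge.cg import parse_cg
from sctoforge.fixtures import FixtureConfig, paper_fixture, random_taxonomy
from sctoforge.rf2 import IS_A, taxonomy_index
from sctoforge.scto import (
    DEFAULT_MAPPING,
    DEFAULT_SCM_RULES,
    And,
    ClassRef,
    DisjointClassesAxiom,
    EquivalentToAxiom,
    Exactly,
    MappingEntry,
    SCMRule,
    SctoError,
    Some,
    SubClassOfAxiom,
    build_scaffold,
    concept_iri,
    reify_nary,
    dump_mapping,
    dump_scm_rules,
    expression_to_axioms,
    load_mapping,
    load_scm_rules,
    mapping_stats,
    materialize_groups,
    reify,
    scm_validate,
    validate_mapping,
)


class TestScaffold:
    def test_object_property_names_match_schema(self):
        ont = build_scaffold()
        assert set(ont.object_properties) == {
            "Has_description", "IsDescriptionOf", "Relationship_destinationId",
            "Relationship_sourceId", "Relationship_typeId", "IsSourceOf",
            "IsDestinationOf", "Grouped_Relations"}

    def test_twenty_data_properties(self):
        assert len(build_scaffold().data_properties) == 20

    def test_three_subclasses_under_component(self):
        ont = build_scaffold()
        children = {ax.subject for ax in ont.class_axioms
                    if isinstance(ax, SubClassOfAxiom)
                    and ax.expr == ClassRef("SCTO_Component")}
        assert children == {"SCTO_138875005", "SCTO_Description", "SCTO_Relationship"}

    def test_one_disjointness_axiom_over_fifteen_hierarchies(self):
        ont = build_scaffold()
        disjoints = [ax for ax in ont.class_axioms
                     if isinstance(ax, DisjointClassesAxiom)]
        assert len(disjoints) == 1 and len(disjoints[0].members) == 15
        assert concept_iri("123037004") not in disjoints[0].members  # body structure

    def test_excluded_hierarchies_produce_no_class(self):
        ont = build_scaffold()
        for sctid in ("48176007", "243796009", "370115009"):
            assert not ont.has_class(concept_iri(sctid))

    def test_linkage_concept_sits_under_root_only(self):
        ont = build_scaffold()
        linkage = concept_iri("106237007")
        supers = [ax.expr.iri for ax in ont.class_axioms
                  if isinstance(ax, SubClassOfAxiom) and ax.subject == linkage]
        assert supers == ["SCTO_138875005"]

    def test_every_class_and_property_has_label_and_definition(self):
        ont = build_scaffold()
        assert all(c.label and c.definition for c in ont.classes.values())
        assert all(p.definition for p in ont.object_properties.values())
        assert all(p.definition for p in ont.data_properties.values())


class TestMapping:
    def test_default_mapping_reproduces_published_shares(self):
        stats = mapping_stats(DEFAULT_MAPPING)
        assert stats["top_level_concepts"] == 19
        assert stats["modeled"] == 16
        assert stats["subsumption_share"] == 82.35
        assert stats["equivalence_share"] == 11.76
        assert stats["no_equivalence_share"] == 5.88

    def test_bad_kind_split_rejected(self):
        broken = tuple(
            MappingEntry(e.sct_id, e.sct_label, "entity", "subsumption")
            if e.kind == "equivalence" else e
            for e in DEFAULT_MAPPING)
        with pytest.raises(SctoError, match="14 subsumption"):
            validate_mapping(broken)

    def test_mapping_yaml_round_trip(self, tmp_path):
        path = tmp_path / "mapping.yaml"
        dump_mapping(DEFAULT_MAPPING, path)
        assert load_mapping(path) == DEFAULT_MAPPING


class TestReify:
    def test_isa_row_becomes_subclass_axiom_not_individual(self, snapshot):
        ont = reify(snapshot, build_scaffold())
        assert SubClassOfAxiom(concept_iri("73211009"),
                               ClassRef(concept_iri("126877002"))) in ont.class_axioms
        assert not any("73211009" in iri and "126877002" in iri
                       for iri in ont.individuals)

    def test_heart_disease_row_becomes_relationship_individual(self, snapshot):
        ont = reify(snapshot, build_scaffold())
        ind = ont.individuals["SCTO_R_2034997023"]
        assert ("Relationship_typeId", concept_iri("363698007")) in ind.object_assertions
        data = {p: v for p, v, _dt in ind.data_assertions}
        assert data["Relationship_relationshipGroup"] == "0"
        assert data["Relationship_active"] == "true"

    def test_description_rows_become_individuals_with_terms(self, snapshot):
        ont = reify(snapshot, build_scaffold())
        ind = ont.individuals["SCTO_D_73211009011"]
        data = {p: v for p, v, _dt in ind.data_assertions}
        assert data["Description_term"] == "diabetes mellitus"
        assert ("IsDescriptionOf", concept_iri("73211009")) in ind.object_assertions

    def test_fully_defined_concept_gets_equivalence(self, snapshot):
        ont = reify(snapshot, build_scaffold())
        equivs = [ax for ax in ont.class_axioms
                  if isinstance(ax, EquivalentToAxiom)
                  and ax.subject == concept_iri("111613008")]
        assert len(equivs) == 1

    def test_empty_snapshot_changes_nothing(self):
        from sctoforge.rf2 import Rf2Snapshot

        before = build_scaffold()
        n_classes = len(before.classes)
        after = reify(Rf2Snapshot(), before)
        assert len(after.classes) == n_classes and not after.individuals

    def test_reify_is_idempotent(self, snapshot):
        ont = reify(snapshot, build_scaffold())
        once = (dict(ont.classes), list(ont.class_axioms), dict(ont.individuals))
        reify(snapshot, ont)
        assert (dict(ont.classes), list(ont.class_axioms), dict(ont.individuals)) == once


class TestMaterializeGroups:
    def test_grouped_fixture_links_morphology_site_pairs(self, snapshot):
        ont = materialize_groups(reify(snapshot, build_scaffold()))
        # tetralogy: 4 groups of 2 rows; skull fracture: 2 groups of 2 rows
        assert len(ont.grouped_pairs()) == 6
        assert all(len(p) == 2 for p in ont.grouped_pairs())  # irreflexive

    def test_ungrouped_variant_yields_no_links_for_tetralogy(self):
        snap = paper_fixture(grouped_tetralogy=False)
        ont = materialize_groups(reify(snap, build_scaffold()))
        assert not any("SCTO_R_72" in a for pair in ont.grouped_pairs() for a in pair)

    def test_symmetry_of_assertions(self, snapshot):
        ont = materialize_groups(reify(snapshot, build_scaffold()))
        assert all((b, a) in ont.grouped_relations for a, b in ont.grouped_relations)

    def test_link_count_matches_combinatorial_formula(self):
        for seed in range(5):
            snap = random_taxonomy(FixtureConfig(seed=seed, n_concepts=30,
                                                 grouped_fraction=0.7,
                                                 rows_per_concept=4))
            ont = materialize_groups(reify(snap, build_scaffold()))
            by_bucket: dict[tuple, int] = {}
            for r in snap.relationships:
                if r.typeId != IS_A and r.relationshipGroup != 0:
                    key = (r.sourceId, r.relationshipGroup)
                    by_bucket[key] = by_bucket.get(key, 0) + 1
            expected = sum(k * (k - 1) // 2 for k in by_bucket.values())
            assert len(ont.grouped_pairs()) == expected


class TestExpressionToAxioms:
    def test_plain_pattern_matches_diabetes_listing_shape(self, snapshot):
        ont = reify(snapshot, build_scaffold())
        expression_to_axioms(parse_cg(ex.DIABETES), "plain", ont, "Diabetes mellitus")
        (axiom,) = [ax for ax in ont.class_axioms
                    if isinstance(ax, SubClassOfAxiom)
                    and ax.subject == "SCTO_EXP_Diabetes_mellitus"]
        members = axiom.expr.members
        assert ClassRef(concept_iri("126877002")) in members
        assert ClassRef(concept_iri("362969004")) in members
        restrictions = [m for m in members if isinstance(m, Some)]
        assert restrictions and all(m.prop == "IsSourceOf" for m in restrictions)

    def test_reified_pattern_pairs_groups_with_cardinality_link(self, snapshot):
        ont = reify(snapshot, build_scaffold())
        expression_to_axioms(parse_cg(ex.CLOSED_SKULL_FRACTURE), "reified", ont,
                             "closed skull fracture with intracranial injury")
        (axiom,) = [ax for ax in ont.class_axioms
                    if isinstance(ax, EquivalentToAxiom)
                    and ax.subject.startswith("SCTO_EXP_closed")]
        group_blocks = [m for m in axiom.expr.members
                        if isinstance(m, Some) and m.prop == "IsSourceOf"
                        and isinstance(m.filler, And)
                        and any(isinstance(x, Exactly) for x in m.filler.members)]
        assert len(group_blocks) == 2
        for block in group_blocks:
            exactly = [x for x in block.filler.members if isinstance(x, Exactly)]
            assert [e.n for e in exactly] == [1]
            assert all(e.prop == "Grouped_Relations" for e in exactly)

    def test_single_focus_without_refinement_is_plain_axiom(self, snapshot):
        ont = reify(snapshot, build_scaffold())
        expression_to_axioms(parse_cg("73211009"), "plain", ont, "just diabetes")
        (axiom,) = [ax for ax in ont.class_axioms
                    if isinstance(ax, EquivalentToAxiom)
                    and ax.subject == "SCTO_EXP_just_diabetes"]
        assert axiom.expr == ClassRef(concept_iri("73211009"))

    def test_unknown_sctid_raises(self, snapshot):
        ont = reify(snapshot, build_scaffold())
        with pytest.raises(SctoError, match="unknown SCTID"):
            expression_to_axioms(parse_cg("999999999"), "plain", ont, "nope")


class TestScmValidate:
    def test_heart_disease_finding_site_is_conformant(self, snapshot, taxonomy):
        expr = parse_cg("56265001: 363698007 = 80891009")
        assert scm_validate(expr, DEFAULT_SCM_RULES, taxonomy) == []

    def test_organism_as_finding_site_is_a_violation(self, taxonomy):
        expr = parse_cg("404684003: 363698007 = 9861002")
        violations = scm_validate(expr, DEFAULT_SCM_RULES, taxonomy)
        assert len(violations) == 1
        assert violations[0].attribute == "363698007"

    def test_source_outside_domain_hierarchy_is_a_violation(self, taxonomy):
        expr = parse_cg("71388002: 363698007 = 80891009")  # procedure, not finding
        violations = scm_validate(expr, DEFAULT_SCM_RULES, taxonomy)
        assert len(violations) == 1
        assert "domain" in violations[0].message

    def test_empty_rule_table_accepts_anything(self, snapshot, taxonomy):
        assert scm_validate(snapshot, (), taxonomy) == []

    def test_snapshot_level_validation_covers_relationship_rows(self, snapshot, taxonomy):
        assert scm_validate(snapshot, DEFAULT_SCM_RULES, taxonomy) == []

    def test_descendant_of_permitted_value_is_permitted(self, taxonomy):
        # heart structure is a strict descendant of anatomical structure
        rule = SCMRule("404684003", "363698007", ("123037004",))
        expr = parse_cg("56265001: 363698007 = 80891009")
        assert scm_validate(expr, (rule,), taxonomy) == []

    def test_scm_yaml_round_trip(self, tmp_path):
        path = tmp_path / "scm.yaml"
        dump_scm_rules(DEFAULT_SCM_RULES, path)
        assert load_scm_rules(path) == DEFAULT_SCM_RULES


class TestReifyNary:
    def test_row_becomes_class_with_location_and_metadata(self, snapshot):
        ont = reify_nary(snapshot, build_scaffold())
        (axiom,) = [ax for ax in ont.class_axioms
                    if isinstance(ax, SubClassOfAxiom)
                    and ax.subject == "SCTO_N_2034997023"]
        members = axiom.expr.members
        assert ClassRef(concept_iri("363698007")) in members
        assert Some("has_location", ClassRef(concept_iri("80891009"))) in members
        assert "has_finding_site" in ont.object_properties

    def test_source_concept_gets_only_restriction(self, snapshot):
        from sctoforge.scto import Only

        ont = reify_nary(snapshot, build_scaffold())
        onlys = [ax for ax in ont.class_axioms
                 if isinstance(ax, SubClassOfAxiom)
                 and ax.subject == concept_iri("56265001")
                 and isinstance(ax.expr, Only)]
        assert onlys and onlys[0].expr.prop == "has_finding_site"

    def test_nary_output_survives_both_profiles(self, snapshot):
        from sctoforge.owl import EmitterProfile, emit

        ont = reify_nary(snapshot, build_scaffold())
        dl_doc = emit(ont, EmitterProfile())
        assert "DataAllValuesFrom(:has_relationshipId" in dl_doc
        el_doc = emit(ont, EmitterProfile(profile="el_safe"))
        assert "DataAllValuesFrom" not in el_doc
        assert "ObjectAllValuesFrom" not in el_doc
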