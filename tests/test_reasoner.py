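"""EL classifier, oracles, counter-model search, redundancy rewrites."""

import random

import pytest

from sctoforge import examples as ex
from sctoforge.cg import parse_cg
from sctoforge.dl import (
    ConceptName,
    Conjunction,
    Existential,
    RoleGroup,
    SubClassOf,
    TBox,
    canonical_form,
    cg_to_dl,
    extension,
    is_model,
)
from sctoforge.fixtures import random_expression, random_tbox
from sctoforge.reasoner import (
    DEFAULT_QUALIFIER_POLICY,
    QualifierPolicy,
    classify,
    equivalent,
    find_countermodel,
    naive_closure,
    rewrite_redundancies,
    subsumes,
)

A, B, C, D = (ConceptName(s) for s in ("1001", "1002", "1003", "1004"))
R, S = "2001", "2002"


class TestClassify:
    def test_fixture_entails_diabetes_under_glucose_disorder(self, fixture_tbox):
        rel = classify(fixture_tbox)
        assert rel.holds("73211009", "126877002")
        assert rel.holds("73211009", "404684003")  # transitively

    def test_every_name_subsumes_itself(self, fixture_tbox):
        rel = classify(fixture_tbox)
        assert all(rel.holds(n, n) for n in fixture_tbox.concept_names)

    def test_monotone_under_axiom_addition(self):
        tbox = random_tbox(3, n_names=10, n_roles=2, n_axioms=10)
        before = classify(tbox).pairs
        extended = tbox.extended([SubClassOf(ConceptName(sorted(tbox.concept_names)[0]),
                                             ConceptName(sorted(tbox.concept_names)[-1]))])
        assert before <= classify(extended).pairs


class TestNaiveClosure:
    def test_empty_tbox_only_reflexive(self):
        tbox = TBox((SubClassOf(A, A), SubClassOf(B, B)))
        rel = naive_closure(tbox)
        assert rel.pairs == {("1001", "1001"), ("1002", "1002")}

    def test_chain_is_transitively_closed(self):
        rel = naive_closure(TBox((SubClassOf(A, B), SubClassOf(B, C))))
        assert rel.holds("1001", "1003")

    def test_agrees_with_classify_on_fixture(self, fixture_tbox):
        assert classify(fixture_tbox).pairs == naive_closure(fixture_tbox).pairs


class TestSubsumes:
    def test_qualification_is_subsumed_by_focus_concept(self, fixture_tbox):
        e7, _ = cg_to_dl(parse_cg(ex.PERIODIC_FEVER))
        assert subsumes(fixture_tbox, e7, ConceptName("274640006"),
                        qualifier_policy=DEFAULT_QUALIFIER_POLICY)

    def test_reflexive_on_arbitrary_expressions(self, fixture_tbox):
        rng = random.Random(1)
        names = sorted(fixture_tbox.concept_names)
        roles = sorted(r for r in fixture_tbox.role_names if r != "RG")
        for _ in range(20):
            e = random_expression(rng, names, roles)
            assert subsumes(fixture_tbox, e, e)

    def test_context_attribute_suppresses_focus_subsumption(self, fixture_tbox):
        # with episodicity declared a context attribute, the qualified
        # expression must no longer count as a fever-with-chills
        e7, _ = cg_to_dl(parse_cg(ex.PERIODIC_FEVER))
        policy = QualifierPolicy(context_attributes=frozenset({"246456000"}))
        assert not subsumes(fixture_tbox, e7, ConceptName("274640006"),
                            qualifier_policy=policy)
        assert not subsumes(fixture_tbox, e7, ConceptName("404684003"),
                            qualifier_policy=policy)  # nor its ancestors

    def test_group_matches_group_via_filler_subsumption(self):
        tbox = TBox((SubClassOf(C, D),))
        specific = RoleGroup((Existential(R, C), Existential(S, A)))
        general = RoleGroup((Existential(R, D), Existential(S, A)))
        assert subsumes(tbox, specific, general)
        assert not subsumes(tbox, general, specific)

    def test_grouped_attribute_also_counts_ungrouped(self):
        tbox = TBox(())
        assert subsumes(tbox, RoleGroup((Existential(R, C),)), Existential(R, C))
        assert not subsumes(tbox, Existential(R, C), RoleGroup((Existential(R, C),)))


class TestEquivalent:
    def test_canonical_form_is_equivalent_to_original(self, fixture_tbox):
        for text in ex.ALL_EXAMPLES.values():
            dl, _ = cg_to_dl(parse_cg(text))
            assert equivalent(fixture_tbox, dl, canonical_form(dl))

    def test_combination_equals_its_normal_form(self, fixture_tbox):
        dl, _ = cg_to_dl(parse_cg(ex.NEEDLE_BIOPSY))
        assert equivalent(fixture_tbox, dl,
                          Conjunction((ConceptName("129249002"), ConceptName("7246002"))))


class TestFindCountermodel:
    def test_none_for_identical_expressions(self):
        tbox = TBox((SubClassOf(A, B),))
        assert find_countermodel(tbox, A, A, max_domain=4) is None

    def test_two_element_countermodel_for_existential_vs_filler(self):
        interp = find_countermodel(TBox(()), Existential(R, C), C, max_domain=2)
        assert interp is not None and len(interp.domain) <= 2
        assert extension(interp, Existential(R, C)) - extension(interp, C)

    def test_max_domain_bound_enforced(self):
        with pytest.raises(ValueError):
            find_countermodel(TBox(()), A, B, max_domain=9)


class TestRewriteRedundancies:
    def test_ungrouped_duplicate_inside_group_dropped(self):
        e = Conjunction((Existential(R, C),
                         RoleGroup((Existential(R, C), Existential(S, D)))))
        out = rewrite_redundancies(TBox(()), e)
        assert out == canonical_form(RoleGroup((Existential(R, C), Existential(S, D))))

    def test_more_general_group_dropped(self):
        tbox = TBox((SubClassOf(C, B),))  # B ⊒ C
        e = Conjunction((RoleGroup((Existential(R, B), Existential(S, D))),
                         RoleGroup((Existential(R, C), Existential(S, D)))))
        out = rewrite_redundancies(tbox, e)
        assert out == canonical_form(RoleGroup((Existential(R, C), Existential(S, D))))

    def test_more_general_sibling_filler_dropped_within_group(self):
        tbox = TBox((SubClassOf(C, B),))
        e = RoleGroup((Existential(R, B), Existential(R, C), Existential(S, D)))
        out = rewrite_redundancies(tbox, e)
        assert out == canonical_form(RoleGroup((Existential(R, C), Existential(S, D))))

    def test_idempotent_and_equivalence_preserving_on_random_expressions(self):
        checked = 0
        for seed in range(1, 11):
            tbox = random_tbox(seed, n_names=10, n_roles=3, n_axioms=12)
            rng = random.Random(seed)
            names = sorted(tbox.concept_names) or ["9100000"]
            roles = sorted(r for r in tbox.role_names if r != "RG") or ["9200000"]
            for _ in range(5):
                e = random_expression(rng, names, roles)
                rewritten = rewrite_redundancies(tbox, e)
                assert rewrite_redundancies(tbox, rewritten) == rewritten
                assert equivalent(tbox, canonical_form(e), rewritten)
                checked += 1
        assert checked == 50


class TestSoundness:
    def test_countermodels_are_semantically_verified(self):
        rng = random.Random(2)
        for seed in range(1, 11):
            tbox = random_tbox(seed, n_names=10, n_roles=3, n_axioms=10)
            names = sorted(tbox.concept_names) or ["9100000"]
            roles = sorted(r for r in tbox.role_names if r != "RG") or ["9200000"]
            for _ in range(5):
                a = random_expression(rng, names, roles)
                b = random_expression(rng, names, roles)
                cm = find_countermodel(tbox, a, b, max_domain=6, seed=seed)
                if cm is not None:
                    assert is_model(cm, tbox)
                    assert extension(cm, a) - extension(cm, b)
                    assert not subsumes(tbox, a, b)
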