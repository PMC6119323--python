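"""Shared test oracles: random CG ASTs and random finite models of a TBox."""

from __future__ import annotations

import random

from sctoforge.cg import CGAttribute, CGExpression, ConceptRef, ConcreteValue
from sctoforge.dl import Interpretation, TBox, is_model
from sctoforge.reasoner import _normalize, _saturate  # noqa: PLC2701 (white-box oracle)


def random_cg_ast(rng: random.Random, depth: int = 1) -> CGExpression:
    """A random valid compositional-grammar AST (terms omitted)."""
    def ref() -> ConceptRef:
        return ConceptRef(str(rng.randint(100000, 999999)))

    def value():
        roll = rng.random()
        if roll < 0.6 or depth == 0:
            return ref()
        if roll < 0.8:
            from decimal import Decimal
            return ConcreteValue("numeric", numeric_value=Decimal(rng.randint(1, 999)))
        return random_cg_ast(rng, depth - 1)

    def attr() -> CGAttribute:
        return CGAttribute(ref(), value())

    focus = tuple(ref() for _ in range(rng.randint(1, 3)))
    ungrouped = tuple(attr() for _ in range(rng.randint(0, 2)))
    groups = tuple(tuple(attr() for _ in range(rng.randint(1, 3)))
                   for _ in range(rng.randint(0, 2)))
    status = "subtype" if rng.random() < 0.3 else "equivalent"
    return CGExpression(status=status, focus=focus, ungrouped=ungrouped, groups=groups)


def random_models_of(tbox: TBox, seed: int, count: int) -> list[Interpretation]:
    """Random finite models of a TBox, verified by ``is_model``.

    Each model is the canonical model of the saturated TBox (one individual
    per atom) extended with randomly chosen clone individuals (bisimilar
    copies of existing ones, with fresh identity), plus random extra role
    edges kept only when the result still satisfies every axiom.  Clones and
    edge noise vary the extensions while model-hood is re-checked
    semantically for every instance produced.
    """
    rng = random.Random(seed)
    sat = _saturate(_normalize(tbox))
    atoms = sorted(sat.norm.atoms - {"⊤", "⊥"})
    base_domain = list(atoms)
    roles = sorted({r for _x, r, _y in sat.edges} | set(tbox.role_names))

    models: list[Interpretation] = []
    while len(models) < count:
        clones = [(f"clone{i}", rng.choice(atoms)) for i in range(rng.randint(0, 5))]
        domain = frozenset(base_domain) | frozenset(c for c, _ in clones)
        member_of = {x: sat.subs.get(x, {x}) for x in base_domain}
        for cid, proto in clones:
            member_of[cid] = sat.subs.get(proto, {proto})
        class_ext = {
            name: frozenset(x for x in domain if name in member_of[x])
            for name in tbox.concept_names}
        edge_pairs: dict[str, set] = {r: set() for r in roles}
        proto_of = dict(clones)
        for x, r, y in sat.edges:
            for sup in sat.norm.super_roles(r):
                if sup in edge_pairs:
                    edge_pairs[sup].add((x, y))
        for cid, proto in clones:
            for x, r, y in sat.edges:
                if x == proto:
                    for sup in sat.norm.super_roles(r):
                        if sup in edge_pairs:
                            edge_pairs[sup].add((cid, y))
        interp = Interpretation(
            domain=domain,
            class_ext=class_ext,
            role_ext={r: frozenset(p) for r, p in edge_pairs.items()},
        )
        assert is_model(interp, tbox), "canonical backbone must satisfy the TBox"
        # random extra edges, kept only if the axioms still hold
        for _ in range(rng.randint(0, 6)):
            r = rng.choice(roles) if roles else None
            if r is None:
                break
            x, y = rng.choice(sorted(domain)), rng.choice(sorted(domain))
            candidate = Interpretation(
                domain=interp.domain,
                class_ext=interp.class_ext,
                role_ext={**interp.role_ext,
                          r: interp.role_ext.get(r, frozenset()) | {(x, y)}},
            )
            if is_model(candidate, tbox):
                interp = candidate
        models.append(interp)
    return models
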