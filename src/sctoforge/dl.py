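"""EL++ construct subset with role groups: types, translation, semantics.

The supported class constructors are ⊤, ⊥, concept names, conjunction,
existential restriction, plus a role-group construct (the braces notation of
compositional grammar) and an opaque concrete-value restriction.  Axioms are
general class inclusions, equivalences, role inclusions, domain/range
restrictions, and pairwise disjointness.  Constructors outside this subset
(negation, disjunction, universal quantification as a class constructor,
inverse roles) are deliberately absent from the type vocabulary.

A role group is internally interchangeable with an existential over the
single reserved role ``RG`` whose filler is the conjunction of the group's
members; that desugaring is what both the finite-model semantics and the
classifier use, so grouped and ungrouped reasoning share one engine.

:class:`Interpretation` is a finite model (domain Δ plus class/role
extensions) and :func:`extension` evaluates a class expression under the
standard set semantics — an executable oracle for everything the reasoner
derives symbolically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cg import (
    CGAttribute,
    CGExpression,
    ConceptRef,
    ConcreteValue,
)
from .rf2 import IS_A, FULLY_DEFINED, Rf2Snapshot, TaxonomyIndex

#: Reserved role name used to desugar role groups.
RG_ROLE = "RG"


class UnsupportedShapeError(ValueError):
    """Expression shape with no rendering on the requested side."""


# ---------------------------------------------------------------------------
# Class expressions


class DLExpression:
    """Base class; concrete variants are frozen dataclasses below."""

    __slots__ = ()


@dataclass(frozen=True)
class Top(DLExpression):
    pass


@dataclass(frozen=True)
class Bottom(DLExpression):
    pass


@dataclass(frozen=True)
class ConceptName(DLExpression):
    sctid: str


@dataclass(frozen=True)
class Conjunction(DLExpression):
    members: tuple[DLExpression, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("conjunction needs at least two members; use the member itself")


@dataclass(frozen=True)
class Existential(DLExpression):
    role: str
    filler: DLExpression


@dataclass(frozen=True)
class ConcreteRestriction(DLExpression):
    """Attribute with a primitive (numeric/string) value.

    Opaque to subsumption except for exact value equality: two restrictions
    are comparable only when role and value coincide.
    """

    role: str
    value: ConcreteValue

    def value_key(self) -> tuple[str, str]:
        if self.value.kind == "numeric":
            return ("numeric", str(self.value.numeric_value))
        return ("string", str(self.value.text_value))


@dataclass(frozen=True)
class RoleGroup(DLExpression):
    """Braces construct: existentials that must be interpreted together."""

    members: tuple[DLExpression, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("role group must be non-empty")
        for m in self.members:
            if not isinstance(m, (Existential, ConcreteRestriction)):
                raise ValueError(
                    f"role-group members must be existential or concrete restrictions, got {m!r}")


TOP = Top()
BOTTOM = Bottom()


def conjunction_of(members: list[DLExpression] | tuple[DLExpression, ...]) -> DLExpression:
    """Conjunction smart constructor: unwraps singletons, rejects empties."""
    members = tuple(members)
    if not members:
        raise ValueError("empty conjunction")
    if len(members) == 1:
        return members[0]
    return Conjunction(members)


def dl_key(expr: DLExpression) -> str:
    """Total, stable ordering key (term-free textual rendering).

    Concept names sort lexicographically on the SCTID string, which is what
    puts ``129249002`` before ``7246002`` in the printed normal form.
    """
    if isinstance(expr, Top):
        return "\x00TOP"
    if isinstance(expr, Bottom):
        return "\x00BOTTOM"
    if isinstance(expr, ConceptName):
        return expr.sctid
    if isinstance(expr, Existential):
        return f"\x01E({expr.role}.{dl_key(expr.filler)})"
    if isinstance(expr, ConcreteRestriction):
        kind, val = expr.value_key()
        return f"\x01V({expr.role}={kind}:{val})"
    if isinstance(expr, RoleGroup):
        return "\x02RG(" + ",".join(dl_key(m) for m in expr.members) + ")"
    if isinstance(expr, Conjunction):
        return "\x03AND(" + ",".join(dl_key(m) for m in expr.members) + ")"
    raise TypeError(f"not a DLExpression: {expr!r}")


def canonical_form(expr: DLExpression) -> DLExpression:
    """Idempotent canonicalization: conjunctions flattened, deduplicated and
    sorted by :func:`dl_key`; fillers and group members canonicalized
    recursively; one-member conjunctions unwrap."""
    if isinstance(expr, (Top, Bottom, ConceptName)):
        return expr
    if isinstance(expr, Existential):
        return Existential(expr.role, canonical_form(expr.filler))
    if isinstance(expr, ConcreteRestriction):
        return expr
    if isinstance(expr, RoleGroup):
        members = sorted({canonical_form(m) for m in expr.members}, key=dl_key)
        return RoleGroup(tuple(members))
    if isinstance(expr, Conjunction):
        flat: list[DLExpression] = []
        for m in expr.members:
            cm = canonical_form(m)
            if isinstance(cm, Conjunction):
                flat.extend(cm.members)
            elif isinstance(cm, Top):
                continue
            else:
                flat.append(cm)
        unique = sorted(set(flat), key=dl_key)
        if not unique:
            return TOP
        return conjunction_of(unique)
    raise TypeError(f"not a DLExpression: {expr!r}")


def desugar_role_groups(expr: DLExpression) -> DLExpression:
    """Replace every role group by ``∃RG.(conjunction of members)`` — and
    keep the members themselves as direct conjuncts.

    The hoisted members reflect what the release data asserts: a grouped
    attribute row still relates the source concept to its value, the group
    only adds the co-occurrence structure.  Hoisting is also what makes the
    redundancy-prevention identities (an ungrouped exists-restriction
    repeated inside a group is redundant, etc.) genuine equivalences.
    """
    if isinstance(expr, RoleGroup):
        members = [desugar_role_groups(m) for m in expr.members]
        return conjunction_of([Existential(RG_ROLE, conjunction_of(members)), *members])
    if isinstance(expr, Conjunction):
        return Conjunction(tuple(desugar_role_groups(m) for m in expr.members))
    if isinstance(expr, Existential):
        return Existential(expr.role, desugar_role_groups(expr.filler))
    return expr


# ---------------------------------------------------------------------------
# TBox axioms


class TBoxAxiom:
    __slots__ = ()


@dataclass(frozen=True)
class SubClassOf(TBoxAxiom):
    lhs: DLExpression
    rhs: DLExpression


@dataclass(frozen=True)
class EquivalentTo(TBoxAxiom):
    """Semantically the pair SubClassOf(lhs, rhs) + SubClassOf(rhs, lhs)."""

    lhs: DLExpression
    rhs: DLExpression


@dataclass(frozen=True)
class RoleInclusion(TBoxAxiom):
    sub: str
    sup: str


@dataclass(frozen=True)
class DomainRestriction(TBoxAxiom):
    """``∃R.⊤ ⊑ C``"""

    role: str
    cls: DLExpression


@dataclass(frozen=True)
class RangeRestriction(TBoxAxiom):
    """``⊤ ⊑ ∀R.C`` (every role filler belongs to C)."""

    role: str
    cls: DLExpression


@dataclass(frozen=True)
class Disjoint(TBoxAxiom):
    """``A ⊓ B ⊑ ⊥``"""

    a: DLExpression
    b: DLExpression


def _walk_expr(expr: DLExpression, names: set[str], roles: set[str]) -> None:
    if isinstance(expr, ConceptName):
        names.add(expr.sctid)
    elif isinstance(expr, Conjunction):
        for m in expr.members:
            _walk_expr(m, names, roles)
    elif isinstance(expr, Existential):
        roles.add(expr.role)
        _walk_expr(expr.filler, names, roles)
    elif isinstance(expr, ConcreteRestriction):
        roles.add(expr.role)
    elif isinstance(expr, RoleGroup):
        roles.add(RG_ROLE)
        for m in expr.members:
            _walk_expr(m, names, roles)


@dataclass
class TBox:
    axioms: tuple[TBoxAxiom, ...]
    concept_names: frozenset[str] = field(init=False)
    role_names: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        names: set[str] = set()
        roles: set[str] = set()
        for ax in self.axioms:
            if isinstance(ax, (SubClassOf, EquivalentTo)):
                _walk_expr(ax.lhs, names, roles)
                _walk_expr(ax.rhs, names, roles)
            elif isinstance(ax, RoleInclusion):
                roles.update((ax.sub, ax.sup))
            elif isinstance(ax, (DomainRestriction, RangeRestriction)):
                roles.add(ax.role)
                _walk_expr(ax.cls, names, roles)
            elif isinstance(ax, Disjoint):
                _walk_expr(ax.a, names, roles)
                _walk_expr(ax.b, names, roles)
            else:
                raise TypeError(f"not a TBoxAxiom: {ax!r}")
        self.concept_names = frozenset(names)
        self.role_names = frozenset(roles)

    def extended(self, extra: list[TBoxAxiom]) -> "TBox":
        return TBox(self.axioms + tuple(extra))


# ---------------------------------------------------------------------------
# Compositional grammar <-> DL translation


def _attr_to_dl(attr: CGAttribute) -> DLExpression:
    value = attr.value
    if isinstance(value, ConceptRef):
        return Existential(attr.name.sctid, ConceptName(value.sctid))
    if isinstance(value, ConcreteValue):
        return ConcreteRestriction(attr.name.sctid, value)
    dl, _kind = cg_to_dl(value)
    return Existential(attr.name.sctid, dl)


def cg_to_dl(expr: CGExpression,
             taxonomy: TaxonomyIndex | None = None) -> tuple[DLExpression, str]:
    """Translate a compositional-grammar AST to its DL form.

    Focus concepts and ungrouped attributes become a conjunction of concept
    names and existentials, each attribute group a role group, nested
    expressions existential fillers, concrete values concrete restrictions.
    The definition status travels alongside as the axiom kind
    (``===`` → equivalent, ``<<<`` → subtype).
    """
    members: list[DLExpression] = [ConceptName(f.sctid) for f in expr.focus]
    members += [_attr_to_dl(a) for a in expr.ungrouped]
    members += [RoleGroup(tuple(_attr_to_dl(a) for a in g)) for g in expr.groups]
    return conjunction_of(members), expr.status


def _filler_to_cg_value(filler: DLExpression):
    if isinstance(filler, ConceptName):
        return ConceptRef(filler.sctid)
    return dl_to_cg(filler)


def dl_to_cg(expr: DLExpression, status: str = "equivalent") -> CGExpression:
    """Inverse translation; only CG-expressible shapes are accepted
    (role groups at the top conjunction level, at least one concept name)."""
    if isinstance(expr, (Top, Bottom)):
        raise UnsupportedShapeError(f"{type(expr).__name__} has no compositional-grammar form")
    if isinstance(expr, ConceptName):
        return CGExpression(status=status, focus=(ConceptRef(expr.sctid),))  # type: ignore[arg-type]

    members = expr.members if isinstance(expr, Conjunction) else (expr,)
    focus: list[ConceptRef] = []
    ungrouped: list[CGAttribute] = []
    groups: list[tuple[CGAttribute, ...]] = []
    for m in members:
        if isinstance(m, ConceptName):
            focus.append(ConceptRef(m.sctid))
        elif isinstance(m, Existential):
            if isinstance(m.filler, RoleGroup):
                raise UnsupportedShapeError(
                    "role group directly as an existential filler has no "
                    "compositional-grammar rendering")
            ungrouped.append(CGAttribute(ConceptRef(m.role), _filler_to_cg_value(m.filler)))
        elif isinstance(m, ConcreteRestriction):
            ungrouped.append(CGAttribute(ConceptRef(m.role), m.value))
        elif isinstance(m, RoleGroup):
            attrs = []
            for g in m.members:
                if isinstance(g, Existential):
                    if isinstance(g.filler, RoleGroup):
                        raise UnsupportedShapeError(
                            "role group nested as a filler inside a group")
                    attrs.append(CGAttribute(ConceptRef(g.role), _filler_to_cg_value(g.filler)))
                else:
                    attrs.append(CGAttribute(ConceptRef(g.role), g.value))
            groups.append(tuple(attrs))
        else:
            raise UnsupportedShapeError(f"no compositional-grammar rendering for {m!r}")
    if not focus:
        raise UnsupportedShapeError("expression without a concept-name conjunct "
                                    "cannot be rendered (focus would be empty)")
    return CGExpression(status=status, focus=tuple(focus),  # type: ignore[arg-type]
                        ungrouped=tuple(ungrouped), groups=tuple(groups))


# ---------------------------------------------------------------------------
# Finite-model semantics


@dataclass
class Interpretation:
    """Finite model I = (Δ, ·^I)."""

    domain: frozenset
    class_ext: dict[str, frozenset] = field(default_factory=dict)
    role_ext: dict[str, frozenset] = field(default_factory=dict)
    #: extension of concrete restrictions, keyed by (role, value-key)
    concrete_ext: dict[tuple, frozenset] = field(default_factory=dict)

    def classes(self, name: str) -> frozenset:
        return self.class_ext.get(name, frozenset())

    def roles(self, name: str) -> frozenset:
        return self.role_ext.get(name, frozenset())


def extension(interp: Interpretation, expr: DLExpression) -> frozenset:
    """Evaluate the set semantics of a class expression.

    Missing names default to the empty extension; role groups evaluate as an
    existential over the reserved ``RG`` role.
    """
    if isinstance(expr, Top):
        return interp.domain
    if isinstance(expr, Bottom):
        return frozenset()
    if isinstance(expr, ConceptName):
        return interp.classes(expr.sctid) & interp.domain
    if isinstance(expr, Conjunction):
        out = interp.domain
        for m in expr.members:
            out &= extension(interp, m)
        return out
    if isinstance(expr, Existential):
        filler = extension(interp, expr.filler)
        return frozenset(x for x, y in interp.roles(expr.role)
                         if x in interp.domain and y in filler)
    if isinstance(expr, ConcreteRestriction):
        return interp.concrete_ext.get((expr.role, expr.value_key()), frozenset()) & interp.domain
    if isinstance(expr, RoleGroup):
        return extension(interp, desugar_role_groups(expr))
    raise TypeError(f"not a DLExpression: {expr!r}")


def _holds(interp: Interpretation, axiom: TBoxAxiom) -> bool:
    if isinstance(axiom, SubClassOf):
        return extension(interp, axiom.lhs) <= extension(interp, axiom.rhs)
    if isinstance(axiom, EquivalentTo):
        return extension(interp, axiom.lhs) == extension(interp, axiom.rhs)
    if isinstance(axiom, RoleInclusion):
        return interp.roles(axiom.sub) <= interp.roles(axiom.sup)
    if isinstance(axiom, DomainRestriction):
        cls = extension(interp, axiom.cls)
        return all(x in cls for x, _ in interp.roles(axiom.role))
    if isinstance(axiom, RangeRestriction):
        cls = extension(interp, axiom.cls)
        return all(y in cls for _, y in interp.roles(axiom.role))
    if isinstance(axiom, Disjoint):
        return not (extension(interp, axiom.a) & extension(interp, axiom.b))
    raise TypeError(f"not a TBoxAxiom: {axiom!r}")


def is_model(interp: Interpretation, tbox: TBox) -> bool:
    """True iff every axiom's semantic condition holds in the interpretation."""
    return all(_holds(interp, ax) for ax in tbox.axioms)


# ---------------------------------------------------------------------------
# RF2 snapshot -> TBox


def snapshot_to_tbox(snapshot: Rf2Snapshot, include_inactive: bool = False) -> TBox:
    """Translate a snapshot's active rows into TBox axioms.

    IS_A rows become name-name subsumptions.  Each concept's non-IS_A rows
    become existentials, with rows sharing a non-zero relationshipGroup
    bundled into a role group.  A fully defined concept gets a single
    equivalence over its parents and role conjuncts; a primitive concept gets
    one subsumption per conjunct.
    """
    axioms: list[TBoxAxiom] = []
    parents: dict[str, list[str]] = {}
    by_source: dict[str, dict[int, list[RelationshipLike]]] = {}

    for r in snapshot.relationships:
        if not r.active and not include_inactive:
            continue
        if r.typeId == IS_A:
            parents.setdefault(r.sourceId, []).append(r.destinationId)
        else:
            by_source.setdefault(r.sourceId, {}).setdefault(r.relationshipGroup, []).append(r)

    for cid, concept in sorted(snapshot.concepts.items()):
        name = ConceptName(cid)
        conjuncts: list[DLExpression] = [ConceptName(p) for p in sorted(parents.get(cid, []))]
        groups = by_source.get(cid, {})
        for gnum in sorted(groups):
            exts = [Existential(r.typeId, ConceptName(r.destinationId))
                    for r in sorted(groups[gnum], key=lambda r: r.id)]
            if gnum == 0:
                conjuncts.extend(exts)
            else:
                conjuncts.append(RoleGroup(tuple(exts)))
        if not conjuncts:
            continue
        if concept.definitionStatusId == FULLY_DEFINED:
            axioms.append(EquivalentTo(name, conjunction_of(conjuncts)))
        else:
            for c in conjuncts:
                axioms.append(SubClassOf(name, c))
    return TBox(tuple(axioms))


# typing helper for snapshot_to_tbox
class RelationshipLike:  # pragma: no cover - annotation aid only
    id: str
    typeId: str
    destinationId: str
    relationshipGroup: int
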