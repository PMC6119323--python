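"""Subsumption and classification by EL completion-rule saturation.

The calculus is the standard polynomial-time completion for EL with general
concept inclusions: the TBox is structurally normalized (fresh names for
complex subexpressions, role groups desugared to the reserved ``RG`` role,
concrete restrictions mapped to opaque per-value atoms), and subsumption sets
``S(X)`` plus role edges ``(X, R, Y)`` are saturated under the usual rules,
with role inclusions closed reflexively-transitively, domain restrictions
internalized as ``∃R.⊤ ⊑ C``, range restrictions applied at existential
introduction, and disjointness producing ⊥-subsumptions that propagate back
along role edges.

Two independent checks accompany the classifier: :func:`naive_closure`
recomputes the same relation by exhaustive unindexed rule application, and
:func:`find_countermodel` probes derivations semantically by building a
canonical finite model (plus seeded random models) and evaluating extensions
with the finite-model oracle in :mod:`sctoforge.dl`.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field

from .dl import (
    Bottom,
    ConceptName,
    ConcreteRestriction,
    Conjunction,
    Disjoint,
    DLExpression,
    DomainRestriction,
    EquivalentTo,
    Existential,
    Interpretation,
    RangeRestriction,
    RG_ROLE,
    RoleGroup,
    RoleInclusion,
    SubClassOf,
    TBox,
    TBoxAxiom,
    Top,
    canonical_form,
    conjunction_of,
    dl_key,
    desugar_role_groups,
    extension,
    is_model,
)

logger = logging.getLogger(__name__)

_TOP = "⊤"
_BOT = "⊥"


@dataclass(frozen=True)
class QualifierPolicy:
    """Context attributes whose presence blocks focus-concept subsumption.

    A qualification like *periodic fever* stays a subtype of its focus
    concept, but context-bearing attributes (e.g. a finding-context of
    "known absent") negate that reading: *known absent asthma* is not an
    asthma.  Expressions carrying one of these attributes at top level are
    not reported as subsumed by their focus concepts or the focus concepts'
    ancestors.
    """

    context_attributes: frozenset[str] = frozenset()


#: Default policy: the finding-context attribute as documented placeholder
#: (the situation hierarchy itself is out of scope).
DEFAULT_QUALIFIER_POLICY = QualifierPolicy(frozenset({"408729009"}))


@dataclass(frozen=True)
class SubsumptionRelation:
    """Reflexive-transitive set of entailed (sub, super) name pairs."""

    names: frozenset[str]
    pairs: frozenset[tuple[str, str]]
    unsatisfiable: frozenset[str] = frozenset()

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def holds(self, sub: str, sup: str) -> bool:
        return (sub, sup) in self.pairs

    def supers(self, name: str) -> frozenset[str]:
        return frozenset(b for a, b in self.pairs if a == name)


# ---------------------------------------------------------------------------
# Normalization


class _Normalizer:
    """Rewrites a TBox into the four EL normal forms over atoms.

    Atoms are original concept names, ``⊤``/``⊥``, fresh structure names
    (``_:n``), and per-value atoms for concrete restrictions.
    """

    def __init__(self) -> None:
        self.told: list[tuple[str, str]] = []            # A ⊑ B
        self.conj: list[tuple[tuple[str, ...], str]] = []  # A1 ⊓ ... ⊓ Ak ⊑ B
        self.exists_rhs: list[tuple[str, str, str]] = []   # A ⊑ ∃R.B
        self.exists_lhs: list[tuple[str, str, str]] = []   # ∃R.A ⊑ B
        self.role_subs: set[tuple[str, str]] = set()
        self.ranges: dict[str, list[str]] = {}
        self._memo: dict[DLExpression, str] = {}
        self._range_filler: dict[tuple[str, str], str] = {}
        self._fresh = itertools.count()
        self.atoms: set[str] = {_TOP, _BOT}
        self.roles: set[str] = set()

    def fresh(self) -> str:
        name = f"_:n{next(self._fresh)}"
        self.atoms.add(name)
        return name

    def atom_of(self, expr: DLExpression) -> str:
        expr = canonical_form(desugar_role_groups(expr))
        return self._atom_of(expr)

    def _atom_of(self, expr: DLExpression) -> str:
        if isinstance(expr, Top):
            return _TOP
        if isinstance(expr, Bottom):
            return _BOT
        if isinstance(expr, ConceptName):
            self.atoms.add(expr.sctid)
            return expr.sctid
        cached = self._memo.get(expr)
        if cached is not None:
            return cached
        if isinstance(expr, ConcreteRestriction):
            # opaque per-value atom: exact equality only
            kind, val = expr.value_key()
            name = f"_:v({expr.role}={kind}:{val})"
            self.atoms.add(name)
            self.roles.add(expr.role)
        elif isinstance(expr, Existential):
            self.roles.add(expr.role)
            filler = self._atom_of(expr.filler)
            name = self.fresh()
            target = self._ranged_filler(expr.role, filler)
            self.exists_rhs.append((name, expr.role, target))
            self.exists_lhs.append((expr.role, filler, name))
        elif isinstance(expr, Conjunction):
            members = tuple(sorted({self._atom_of(m) for m in expr.members}))
            name = self.fresh()
            for m in members:
                self.told.append((name, m))
            self.conj.append((members, name))
        else:
            raise TypeError(f"unsupported construct in normalization: {expr!r}")
        self._memo[expr] = name
        return name

    def _ranged_filler(self, role: str, filler: str) -> str:
        """Apply range restrictions at existential introduction: the edge
        target is a name subsumed by the filler and by every applicable
        range class."""
        applicable = sorted(
            rng for sup in self.super_roles(role) for rng in self.ranges.get(sup, []))
        if not applicable:
            return filler
        key = (role, filler)
        cached = self._range_filler.get(key)
        if cached is None:
            cached = self.fresh()
            self.told.append((cached, filler))
            for rng in applicable:
                self.told.append((cached, rng))
            self._range_filler[key] = cached
        return cached

    def super_roles(self, role: str) -> set[str]:
        out = {role}
        changed = True
        while changed:
            changed = False
            for sub, sup in self.role_subs:
                if sub in out and sup not in out:
                    out.add(sup)
                    changed = True
        return out

    def add_axiom(self, axiom: TBoxAxiom) -> None:
        if isinstance(axiom, SubClassOf):
            self.told.append((self.atom_of(axiom.lhs), self.atom_of(axiom.rhs)))
        elif isinstance(axiom, EquivalentTo):
            a, b = self.atom_of(axiom.lhs), self.atom_of(axiom.rhs)
            self.told.append((a, b))
            self.told.append((b, a))
        elif isinstance(axiom, Disjoint):
            a, b = self.atom_of(axiom.a), self.atom_of(axiom.b)
            self.conj.append((tuple(sorted({a, b})), _BOT))
        elif isinstance(axiom, DomainRestriction):
            self.roles.add(axiom.role)
            self.exists_lhs.append((axiom.role, _TOP, self.atom_of(axiom.cls)))
        elif isinstance(axiom, RangeRestriction):
            pass  # collected in a first pass
        elif isinstance(axiom, RoleInclusion):
            pass  # collected in a first pass
        else:
            raise TypeError(f"unsupported axiom: {axiom!r}")


def _normalize(tbox: TBox, extra: list[TBoxAxiom] = []) -> _Normalizer:
    norm = _Normalizer()
    axioms = list(tbox.axioms) + list(extra)
    # role hierarchy and ranges first: they parameterize ∃-introduction
    for ax in axioms:
        if isinstance(ax, RoleInclusion):
            norm.role_subs.add((ax.sub, ax.sup))
            norm.roles.update((ax.sub, ax.sup))
        elif isinstance(ax, RangeRestriction):
            norm.roles.add(ax.role)
            norm.ranges.setdefault(ax.role, []).append(norm.atom_of(ax.cls))
    for ax in axioms:
        norm.add_axiom(ax)
    return norm


# ---------------------------------------------------------------------------
# Saturation (worklist classifier)


@dataclass
class _Saturation:
    subs: dict[str, set[str]]
    edges: set[tuple[str, str, str]]
    norm: _Normalizer

    def entails(self, a: str, b: str) -> bool:
        return b in self.subs.get(a, ())


def _saturate(norm: _Normalizer) -> _Saturation:
    subs: dict[str, set[str]] = {a: {a, _TOP} for a in norm.atoms}
    edges: set[tuple[str, str, str]] = set()
    edges_by_target: dict[str, set[tuple[str, str]]] = {}
    edges_by_source: dict[str, set[tuple[str, str]]] = {}

    told_ix: dict[str, list[str]] = {}
    for a, b in norm.told:
        told_ix.setdefault(a, []).append(b)
    conj_ix: dict[str, list[tuple[tuple[str, ...], str]]] = {}
    for members, b in norm.conj:
        for m in members:
            conj_ix.setdefault(m, []).append((members, b))
    rhs_ix: dict[str, list[tuple[str, str]]] = {}
    for a, r, b in norm.exists_rhs:
        rhs_ix.setdefault(a, []).append((r, b))
    lhs_ix: dict[str, list[tuple[str, str]]] = {}  # role -> [(filler, out)]
    for r, a, b in norm.exists_lhs:
        lhs_ix.setdefault(r, []).append((a, b))
    supers_of_role = {r: norm.super_roles(r) for r in norm.roles}

    work: list[tuple[str, str]] = [(x, s) for x, ss in subs.items() for s in ss]

    def add_sub(x: str, s: str) -> None:
        if s not in subs.setdefault(x, {x, _TOP}):
            subs[x].add(s)
            work.append((x, s))

    def add_edge(x: str, r: str, y: str) -> None:
        if (x, r, y) in edges:
            return
        edges.add((x, r, y))
        edges_by_target.setdefault(y, set()).add((x, r))
        edges_by_source.setdefault(x, set()).add((r, y))
        # existential-elimination for the new edge
        for sup in supers_of_role.get(r, {r}):
            for filler, out in lhs_ix.get(sup, ()):  # ∃sup.filler ⊑ out
                if filler in subs.get(y, ()):
                    add_sub(x, out)
        if _BOT in subs.get(y, ()):
            add_sub(x, _BOT)

    while work:
        x, s = work.pop()
        for b in told_ix.get(s, ()):
            add_sub(x, b)
        for members, b in conj_ix.get(s, ()):
            if all(m in subs[x] for m in members):
                add_sub(x, b)
        for r, b in rhs_ix.get(s, ()):
            add_edge(x, r, b)
        # s newly in S(y): re-check edges pointing at y=x
        for src, r in edges_by_target.get(x, ()):
            for sup in supers_of_role.get(r, {r}):
                for filler, out in lhs_ix.get(sup, ()):
                    if filler == s:
                        add_sub(src, out)
        if s == _BOT:
            for src, _r in edges_by_target.get(x, ()):
                add_sub(src, _BOT)

    return _Saturation(subs, edges, norm)


def _relation_from(sat: _Saturation, names: frozenset[str]) -> SubsumptionRelation:
    pairs: set[tuple[str, str]] = set()
    unsat: set[str] = set()
    for a in names:
        ss = sat.subs.get(a, {a})
        if _BOT in ss:
            unsat.add(a)
            pairs.update((a, b) for b in names)
        else:
            pairs.update((a, b) for b in ss if b in names)
        pairs.add((a, a))
    if unsat:
        logger.warning("unsatisfiable concept name(s): %s", ", ".join(sorted(unsat)))
    return SubsumptionRelation(names=names, pairs=frozenset(pairs),
                               unsatisfiable=frozenset(unsat))


def classify(tbox: TBox) -> SubsumptionRelation:
    """All entailed name-name subsumptions, reflexively-transitively closed."""
    sat = _saturate(_normalize(tbox))
    return _relation_from(sat, tbox.concept_names)


# ---------------------------------------------------------------------------
# Naive oracle: exhaustive unindexed rule application


def naive_closure(tbox: TBox) -> SubsumptionRelation:
    """Same relation as :func:`classify`, computed the slow way: every rule
    is re-tried against every atom on every pass until nothing changes."""
    norm = _normalize(tbox)
    atoms = sorted(norm.atoms)
    role_closure: set[tuple[str, str]] = {(r, r) for r in norm.roles}
    role_closure |= set(norm.role_subs)
    changed = True
    while changed:  # transitive closure of the role hierarchy
        changed = False
        for (a, b), (c, d) in itertools.product(list(role_closure), repeat=2):
            if b == c and (a, d) not in role_closure:
                role_closure.add((a, d))
                changed = True

    subs: dict[str, set[str]] = {a: {a, _TOP} for a in atoms}
    edges: set[tuple[str, str, str]] = set()
    changed = True
    while changed:
        changed = False
        for x in atoms:
            for a, b in norm.told:
                if a in subs[x] and b not in subs[x]:
                    subs[x].add(b); changed = True
            for members, b in norm.conj:
                if b not in subs[x] and all(m in subs[x] for m in members):
                    subs[x].add(b); changed = True
            for a, r, b in norm.exists_rhs:
                if a in subs[x] and (x, r, b) not in edges:
                    edges.add((x, r, b)); changed = True
        for (x, r, y) in list(edges):
            for r2, a, b in norm.exists_lhs:
                if (r, r2) in role_closure and a in subs[y] and b not in subs[x]:
                    subs[x].add(b); changed = True
            if _BOT in subs[y] and _BOT not in subs[x]:
                subs[x].add(_BOT); changed = True

    sat = _Saturation(subs, edges, norm)
    return _relation_from(sat, tbox.concept_names)


# ---------------------------------------------------------------------------
# Expression-level subsumption


_FRESH_SUB = "_:querySub"
_FRESH_SUP = "_:querySup"


def _internalized(tbox: TBox, a: DLExpression, b: DLExpression) -> _Saturation:
    extra: list[TBoxAxiom] = [
        EquivalentTo(ConceptName(_FRESH_SUB[2:]), a),
        EquivalentTo(ConceptName(_FRESH_SUP[2:]), b),
    ]
    return _saturate(_normalize(tbox, extra))


def _top_level_roles(expr: DLExpression) -> set[str]:
    members = expr.members if isinstance(expr, Conjunction) else (expr,)
    roles: set[str] = set()
    for m in members:
        if isinstance(m, (Existential, ConcreteRestriction)):
            roles.add(m.role)
        elif isinstance(m, RoleGroup):
            roles.update(g.role for g in m.members
                         if isinstance(g, (Existential, ConcreteRestriction)))
    return roles


def _focus_names(expr: DLExpression) -> set[str]:
    members = expr.members if isinstance(expr, Conjunction) else (expr,)
    return {m.sctid for m in members if isinstance(m, ConceptName)}


def subsumes(tbox: TBox, a: DLExpression, b: DLExpression,
             qualifier_policy: QualifierPolicy | None = None) -> bool:
    """Does the TBox entail ``a ⊑ b``?  Decided by internalization: fresh
    names are defined equivalent to both expressions and the extended TBox
    is classified.

    When ``a`` carries a context attribute from the qualifier policy at top
    level, subsumption by its focus concepts (or their ancestors) is
    suppressed: a finding asserted in a negating context is not an instance
    of the finding itself.
    """
    a = canonical_form(a)
    b = canonical_form(b)
    sat = _internalized(tbox, a, b)
    result = sat.entails(_FRESH_SUB[2:], _FRESH_SUP[2:])
    if not result or qualifier_policy is None:
        return result
    if isinstance(b, ConceptName) and (_top_level_roles(a) & qualifier_policy.context_attributes):
        for focus in _focus_names(a):
            if b.sctid == focus or sat.entails(focus, b.sctid):
                return False
    return result


def equivalent(tbox: TBox, a: DLExpression, b: DLExpression) -> bool:
    """``a ⊑ b`` and ``b ⊑ a``."""
    return subsumes(tbox, a, b) and subsumes(tbox, b, a)


# ---------------------------------------------------------------------------
# Counter-model search


def _canonical_interpretation(sat: _Saturation, names: frozenset[str],
                              root: str) -> Interpretation | None:
    """Generated submodel of the canonical model, reachable from ``root``,
    minimized by bisimulation quotient over the visible signature.

    Extensions of the supported class constructors are invariant under
    bisimulation, and every TBox axiom mentions only visible names and
    roles, so identifying bisimilar nodes preserves model-hood and the
    witness; the quotient shrinks the domain to the number of bisimulation
    classes.  The caller re-verifies the result semantically regardless.
    """
    reachable = {root}
    frontier = [root]
    out_edges: dict[str, list[tuple[str, str]]] = {}
    for x, r, y in sat.edges:
        out_edges.setdefault(x, []).append((r, y))
    while frontier:
        x = frontier.pop()
        for _r, y in out_edges.get(x, ()):
            if y not in reachable:
                reachable.add(y)
                frontier.append(y)
    if _BOT in sat.subs.get(root, ()):
        return None  # root unsatisfiable: every model makes its extension empty

    concrete_atoms = {a for a in sat.norm.atoms if a.startswith("_:v(")}
    visible = set(names) | concrete_atoms

    def label(node: str) -> frozenset:
        return frozenset(sat.subs.get(node, {node}) & visible)

    # partition refinement: initial blocks by visible label, refined by the
    # multiset of (role, successor-block) signatures until stable
    block: dict[str, int] = {}
    blocks_of_label: dict[frozenset, int] = {}
    for node in sorted(reachable):
        block[node] = blocks_of_label.setdefault(label(node), len(blocks_of_label))
    while True:
        signature: dict[str, tuple] = {}
        for node in reachable:
            sig = frozenset((r, block[y]) for r, y in out_edges.get(node, ())
                            if y in reachable)
            signature[node] = (block[node], sig)
        new_ids: dict[tuple, int] = {}
        new_block = {node: new_ids.setdefault(signature[node], len(new_ids))
                     for node in sorted(reachable)}
        if len(new_ids) == len(set(block.values())):
            break
        block = new_block

    rep: dict[str, str] = {}
    rep_of_block: dict[int, str] = {}
    for node in sorted(reachable):
        rep[node] = rep_of_block.setdefault(block[node], node)

    domain = frozenset(rep.values())
    class_ext: dict[str, frozenset] = {}
    for name in names:
        class_ext[name] = frozenset(
            r for r in domain if name in sat.subs.get(r, ()))
    role_ext: dict[str, frozenset] = {}
    for x, r, y in sat.edges:
        if x in reachable and y in reachable:
            for sup in sat.norm.super_roles(r):
                role_ext[sup] = role_ext.get(sup, frozenset()) | {(rep[x], rep[y])}
    concrete_ext: dict[tuple, frozenset] = {}
    for atom in sat.norm.atoms:
        if atom.startswith("_:v("):
            body = atom[4:-1]
            role, _, rest = body.partition("=")
            kind, _, val = rest.partition(":")
            concrete_ext[(role, (kind, val))] = frozenset(
                r for r in domain if atom in sat.subs.get(r, ()))
    return Interpretation(domain=domain, class_ext=class_ext,
                          role_ext=role_ext, concrete_ext=concrete_ext)


def _merge_individuals(interp: Interpretation, keep, drop) -> Interpretation:
    """Collapse ``drop`` into ``keep`` (class memberships union, edges
    redirected); validity is re-checked by the caller, never assumed."""
    def subst(x):
        return keep if x == drop else x

    return Interpretation(
        domain=interp.domain - {drop},
        class_ext={n: frozenset(subst(x) for x in ext)
                   for n, ext in interp.class_ext.items()},
        role_ext={r: frozenset((subst(x), subst(y)) for x, y in pairs)
                  for r, pairs in interp.role_ext.items()},
        concrete_ext={k: frozenset(subst(x) for x in ext)
                      for k, ext in interp.concrete_ext.items()},
    )


def _shrink_to(interp: Interpretation, max_domain: int, tbox: TBox,
               a: DLExpression, b: DLExpression) -> Interpretation | None:
    """Greedily merge individuals while the result stays a verified
    counter-model; None when the bound cannot be reached."""
    cur = interp
    while len(cur.domain) > max_domain:
        merged = None
        ordered = sorted(cur.domain, key=str)
        for keep in ordered:
            for drop in ordered:
                if keep == drop:
                    continue
                cand = _merge_individuals(cur, keep, drop)
                if (extension(cand, a) - extension(cand, b)) and is_model(cand, tbox):
                    merged = cand
                    break
            if merged is not None:
                break
        if merged is None:
            return None
        cur = merged
    return cur


def _concrete_keys(expr: DLExpression, out: set[tuple]) -> None:
    if isinstance(expr, ConcreteRestriction):
        out.add((expr.role, expr.value_key()))
    elif isinstance(expr, Conjunction):
        for m in expr.members:
            _concrete_keys(m, out)
    elif isinstance(expr, Existential):
        _concrete_keys(expr.filler, out)
    elif isinstance(expr, RoleGroup):
        for m in expr.members:
            _concrete_keys(m, out)


def find_countermodel(tbox: TBox, a: DLExpression, b: DLExpression,
                      max_domain: int = 6, seed: int = 0,
                      random_attempts: int = 200) -> Interpretation | None:
    """Look for a model of the TBox in which some individual falls in
    ``extension(a)`` but not ``extension(b)``.

    Strategy: build the canonical model from completion saturation and
    verify it semantically with the Table-1 evaluator (complete for the
    supported fragment whenever the reachable part fits in ``max_domain``),
    then probe seeded random interpretations.  Every returned model has been
    checked by :func:`sctoforge.dl.is_model` and witnessed by
    :func:`sctoforge.dl.extension`; the search never trusts the classifier.
    """
    if max_domain > 8:
        raise ValueError("max_domain above 8 is not supported (cost bound)")
    a = canonical_form(a)
    b = canonical_form(b)
    sat = _internalized(tbox, a, b)
    root = _FRESH_SUB[2:]
    names = tbox.concept_names | {n for n in sat.norm.atoms if not n.startswith("_:")
                                  and n not in (_TOP, _BOT)}

    interp = _canonical_interpretation(sat, frozenset(names), root)
    if interp is not None:
        ext_a = extension(interp, a)
        ext_b = extension(interp, b)
        if (ext_a - ext_b) and is_model(interp, tbox):
            if len(interp.domain) <= max_domain:
                return interp
            shrunk = _shrink_to(interp, max_domain, tbox, a, b)
            if shrunk is not None:
                return shrunk

    rng = random.Random(seed)
    sig_names = sorted(names - {_FRESH_SUB[2:], _FRESH_SUP[2:]})
    sig_roles = sorted(tbox.role_names | {RG_ROLE} |
                       {r for r in sat.norm.roles if not r.startswith("_:")})
    keys: set[tuple] = set()
    _concrete_keys(a, keys)
    _concrete_keys(b, keys)
    for _ in range(random_attempts):
        size = rng.randint(1, max_domain)
        domain = frozenset(range(size))
        class_ext = {n: frozenset(x for x in domain if rng.random() < 0.5)
                     for n in sig_names}
        role_ext = {r: frozenset((x, y) for x in domain for y in domain
                                 if rng.random() < 0.3)
                    for r in sig_roles}
        concrete_ext = {k: frozenset(x for x in domain if rng.random() < 0.5)
                        for k in keys}
        cand = Interpretation(domain=domain, class_ext=class_ext,
                              role_ext=role_ext, concrete_ext=concrete_ext)
        if not is_model(cand, tbox):
            continue
        if extension(cand, a) - extension(cand, b):
            return cand
    return None


# ---------------------------------------------------------------------------
# Redundancy elimination


def _ge(tbox: TBox, rel: SubsumptionRelation,
        c1: DLExpression, c2: DLExpression) -> bool:
    """c1 ⊒ c2, using the cached name-name relation when both are names."""
    if isinstance(c1, ConceptName) and isinstance(c2, ConceptName):
        return rel.holds(c2.sctid, c1.sctid)
    return subsumes(tbox, c2, c1)


def _member_ge(tbox: TBox, rel: SubsumptionRelation,
               m1: DLExpression, m2: DLExpression) -> bool:
    """Is group/ungrouped member m1 more general than (or equal to) m2?"""
    if isinstance(m1, Existential) and isinstance(m2, Existential):
        return m1.role == m2.role and _ge(tbox, rel, m1.filler, m2.filler)
    return m1 == m2



def _prune_group(tbox: TBox, rel: SubsumptionRelation,
                 members: tuple[DLExpression, ...]) -> tuple[DLExpression, ...]:
    """Rule (3): inside a group, drop an existential whose filler is more
    general than a sibling's on the same role."""
    kept = list(members)
    for m1 in list(kept):
        for m2 in kept:
            if m1 is m2 or m1 not in kept:
                continue
            if not (isinstance(m1, Existential) and isinstance(m2, Existential)):
                continue
            if m1.role != m2.role:
                continue
            ge12 = _ge(tbox, rel, m1.filler, m2.filler)
            ge21 = _ge(tbox, rel, m2.filler, m1.filler)
            if ge12 and (not ge21 or dl_key(m2) < dl_key(m1)):
                kept.remove(m1)
                break
    return tuple(kept)


def _rewrite_level(tbox: TBox, rel: SubsumptionRelation,
                   expr: DLExpression) -> DLExpression:
    # recurse into fillers first (nested groups follow the same rules)
    if isinstance(expr, Existential):
        return Existential(expr.role, _rewrite_level(tbox, rel, expr.filler))
    if isinstance(expr, RoleGroup):
        members = tuple(_rewrite_level(tbox, rel, m) for m in expr.members)
        return RoleGroup(_prune_group(tbox, rel, members))
    if not isinstance(expr, Conjunction):
        return expr

    members = [_rewrite_level(tbox, rel, m) for m in expr.members]
    groups = [m for m in members if isinstance(m, RoleGroup)]
    rest = [m for m in members if not isinstance(m, RoleGroup)]

    # rule (2): drop a group whose content is entailed by another group
    kept_groups = list(groups)
    for g1 in list(kept_groups):
        for g2 in kept_groups:
            if g1 is g2 or g1 not in kept_groups:
                continue
            body1 = conjunction_of(g1.members)
            body2 = conjunction_of(g2.members)
            le = subsumes(tbox, body2, body1)   # g2 more specific
            ge = subsumes(tbox, body1, body2)
            if le and (not ge or dl_key(g2) < dl_key(g1)):
                kept_groups.remove(g1)
                break

    # rule (1): drop an ungrouped existential duplicated inside a group
    kept_rest = []
    grouped_members = {m for g in kept_groups for m in g.members}
    for m in rest:
        if isinstance(m, Existential) and m in grouped_members:
            continue
        kept_rest.append(m)

    out = kept_rest + kept_groups
    if not out:
        return expr
    return conjunction_of(out)


def rewrite_redundancies(tbox: TBox, expr: DLExpression) -> DLExpression:
    """Apply the three redundancy-prevention rewrites to fixpoint.

    (1) an ungrouped exists-restriction repeated inside a group is dropped;
    (2) a group repeating another group with more general classes is dropped;
    (3) within a group, an exists-restriction with a more general filler on
    the same role as a sibling is dropped.  Rules run innermost-first (3),
    then (2), then (1), with canonicalization between passes; each rule only
    removes semantically redundant conjuncts, so the fixpoint is unique.
    """
    rel = classify(tbox)
    current = canonical_form(expr)
    while True:
        rewritten = canonical_form(_rewrite_level(tbox, rel, current))
        if rewritten == current:
            return current
        current = rewritten
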