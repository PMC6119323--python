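"""Self-contained miniature RF2 snapshots and seeded random test structures.

:func:`paper_fixture` builds a deterministic snapshot containing every
concept, description, and relationship used by the worked examples in
:mod:`sctoforge.examples` — including the tetralogy-of-Fallot rows in both
their grouped and ungrouped modelling — so the whole toolchain runs without
a licensed SNOMED CT release.  Taxonomy placements the examples state
explicitly are distinguished from placements this fixture invents by a
sidecar manifest (``synthetic=true`` entries).

:func:`random_taxonomy`, :func:`random_tbox`, :func:`random_expression`
and :func:`random_interpretation` produce seeded random structures for
stress and oracle testing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .dl import (
    ConceptName,
    Conjunction,
    Disjoint,
    DLExpression,
    DomainRestriction,
    Existential,
    Interpretation,
    RangeRestriction,
    RoleGroup,
    RoleInclusion,
    SubClassOf,
    TBox,
    TBoxAxiom,
    conjunction_of,
)
from .rf2 import (
    FSN_TYPE,
    FULLY_DEFINED,
    IS_A,
    PRIMITIVE,
    ConceptRow,
    DescriptionRow,
    RelationshipRow,
    Rf2Snapshot,
)

_ET = "20150731"
_MODULE = "900000000000207008"
_CASE = "900000000000448009"
_CHARACTERISTIC = "900000000000011006"
_MODIFIER = "900000000000451002"

ROOT = "138875005"

# (sctid, fsn, parents, provenance of placement, definition status)
# provenance: "printed" = the example text states the edge; "implied" = the
# example semantics force the hierarchy; "synthetic" = fixture invention.
_CONCEPTS: tuple[tuple[str, str, tuple[str, ...], str, str], ...] = (
    (ROOT, "SNOMED CT Concept", (), "printed", PRIMITIVE),
    # top-level hierarchies used by the examples
    ("404684003", "clinical finding", (ROOT,), "implied", PRIMITIVE),
    ("71388002", "procedure", (ROOT,), "printed", PRIMITIVE),
    ("123037004", "body structure", (ROOT,), "implied", PRIMITIVE),
    ("410607006", "organism", (ROOT,), "implied", PRIMITIVE),
    ("105590001", "substance", (ROOT,), "implied", PRIMITIVE),
    ("373873005", "pharmaceutical / biologic product", (ROOT,), "implied", PRIMITIVE),
    ("260787004", "physical object", (ROOT,), "implied", PRIMITIVE),
    ("362981000", "qualifier value", (ROOT,), "implied", PRIMITIVE),
    ("106237007", "linkage concept", (ROOT,), "implied", PRIMITIVE),
    # attribute (linkage) hierarchy
    ("246061005", "attribute", ("106237007",), "implied", PRIMITIVE),
    ("410662002", "concept model attribute", ("246061005",), "implied", PRIMITIVE),
    ("116680003", "is a", ("410662002",), "implied", PRIMITIVE),
    ("363698007", "finding site", ("410662002",), "implied", PRIMITIVE),
    ("405815000", "procedure device", ("410662002",), "implied", PRIMITIVE),
    ("260686004", "method", ("410662002",), "implied", PRIMITIVE),
    ("405813007", "procedure site - direct", ("410662002",), "implied", PRIMITIVE),
    ("116676008", "associated morphology", ("410662002",), "implied", PRIMITIVE),
    ("411116001", "has dose form", ("410662002",), "implied", PRIMITIVE),
    ("127489000", "has active ingredient", ("410662002",), "implied", PRIMITIVE),
    ("111115", "has basis of strength", ("410662002",), "printed", PRIMITIVE),
    ("246456000", "episodicity", ("410662002",), "implied", PRIMITIVE),
    ("246075003", "causative agent", ("410662002",), "implied", PRIMITIVE),
    ("272741003", "laterality", ("410662002",), "implied", PRIMITIVE),
    # body structures
    ("91723000", "anatomical structure", ("123037004",), "synthetic", PRIMITIVE),
    ("280115004", "acquired body structure", ("123037004",), "synthetic", PRIMITIVE),
    ("49755003", "morphologically abnormal structure", ("123037004",), "synthetic", PRIMITIVE),
    ("113331007", "structure of endocrine system", ("91723000",), "implied", PRIMITIVE),
    ("181940002", "radius", ("91723000",), "implied", PRIMITIVE),
    ("15497006", "ovarian structure", ("91723000",), "implied", PRIMITIVE),
    ("128319008", "intracranial structure", ("91723000",), "implied", PRIMITIVE),
    ("89546000", "bone structure of cranium", ("91723000",), "implied", PRIMITIVE),
    ("45653009", "structure of upper lobe of lung", ("91723000",), "implied", PRIMITIVE),
    ("80891009", "heart structure", ("91723000",), "implied", PRIMITIVE),
    ("589001", "interventricular septum structure", ("91723000",), "synthetic", PRIMITIVE),
    ("39057004", "pulmonary valve structure", ("91723000",), "synthetic", PRIMITIVE),
    ("113262008", "thoracic aorta structure", ("91723000",), "synthetic", PRIMITIVE),
    ("53085002", "right cardiac ventricular structure", ("91723000",), "synthetic", PRIMITIVE),
    ("450695007", "closed traumatic abnormality", ("49755003",), "implied", PRIMITIVE),
    ("20946005", "fracture, closed", ("49755003",), "implied", PRIMITIVE),
    ("6920004", "defect", ("49755003",), "synthetic", PRIMITIVE),
    ("415582006", "stenosis", ("49755003",), "synthetic", PRIMITIVE),
    ("30812002", "overriding structures", ("49755003",), "synthetic", PRIMITIVE),
    ("56246009", "hypertrophy", ("49755003",), "synthetic", PRIMITIVE),
    # clinical findings
    ("126877002", "disorder of glucose metabolism", ("404684003",), "implied", PRIMITIVE),
    ("362969004", "disorder of endocrine system", ("404684003",), "implied", PRIMITIVE),
    ("73211009", "diabetes mellitus", ("126877002", "362969004"), "printed", PRIMITIVE),
    ("125605004", "fracture of bone", ("404684003",), "implied", PRIMITIVE),
    ("451000119106", "closed injury of head", ("404684003",), "implied", PRIMITIVE),
    ("371162008", "closed fracture of skull", ("404684003",), "implied", PRIMITIVE),
    ("111613008", "closed skull fracture with intracranial injury",
     ("451000119106", "371162008"), "printed", FULLY_DEFINED),
    ("274640006", "fever with chills", ("404684003",), "implied", PRIMITIVE),
    ("87628006", "bacterial infectious disease", ("404684003",), "implied", PRIMITIVE),
    ("56265001", "heart disease", ("404684003",), "implied", PRIMITIVE),
    ("86299006", "tetralogy of Fallot", ("56265001",), "synthetic", PRIMITIVE),
    # procedures
    ("7246002", "kidney biopsy", ("71388002",), "implied", PRIMITIVE),
    ("129249002", "needle biopsy", ("71388002",), "implied", PRIMITIVE),
    # qualifier values
    ("129304002", "excision - action", ("362981000",), "implied", PRIMITIVE),
    ("81591007", "periodic", ("362981000",), "implied", PRIMITIVE),
    ("385049006", "capsule", ("362981000",), "implied", PRIMITIVE),
    ("258684004", "mg", ("362981000",), "implied", PRIMITIVE),
    ("7771000", "left", ("362981000",), "implied", PRIMITIVE),
    # others
    ("122456005", "laser device", ("260787004",), "implied", PRIMITIVE),
    ("9861002", "streptococcus pneumonia", ("410607006",), "implied", PRIMITIVE),
    ("372687004", "amoxicillin", ("105590001",), "implied", PRIMITIVE),
    ("27658006", "amoxicillin", ("373873005",), "implied", PRIMITIVE),
)

# non-IS_A relationship rows: (id, sourceId, typeId, destinationId, group, provenance)
_TETRALOGY_GROUPS: tuple[tuple[str, str, int], ...] = (
    ("116676008", "6920004", 1), ("363698007", "589001", 1),
    ("116676008", "415582006", 2), ("363698007", "39057004", 2),
    ("116676008", "30812002", 3), ("363698007", "113262008", 3),
    ("116676008", "56246009", 4), ("363698007", "53085002", 4),
)

_ATTRIBUTE_ROWS: tuple[tuple[str, str, str, str, int, str], ...] = (
    ("2034997023", "56265001", "363698007", "80891009", 0, "printed"),
    ("700000000000101", "73211009", "363698007", "113331007", 0, "printed"),
    ("700000000000102", "111613008", "116676008", "450695007", 1, "printed"),
    ("700000000000103", "111613008", "363698007", "128319008", 1, "printed"),
    ("700000000000104", "111613008", "116676008", "20946005", 2, "printed"),
    ("700000000000105", "111613008", "363698007", "89546000", 2, "printed"),
)


def paper_fixture(grouped_tetralogy: bool = True) -> Rf2Snapshot:
    """The deterministic worked-example snapshot.

    ``grouped_tetralogy=False`` reproduces the ungrouped modelling variant
    (all tetralogy rows in relationshipGroup 0); the default uses four
    morphology/site groups.
    """
    snap = Rf2Snapshot()
    for sctid, fsn, parents, _prov, status in _CONCEPTS:
        snap.add_concept(ConceptRow(sctid, _ET, True, _MODULE, status))
        snap.descriptions.append(DescriptionRow(
            sctid + "011", _ET, True, _MODULE, sctid, "en", FSN_TYPE, fsn, _CASE))

    rel_counter = 0
    for sctid, _fsn, parents, _prov, _status in _CONCEPTS:
        for parent in parents:
            rel_counter += 1
            snap.relationships.append(RelationshipRow(
                str(710000000000000 + rel_counter), _ET, True, _MODULE,
                sctid, parent, 0, IS_A, _CHARACTERISTIC, _MODIFIER))

    for rid, src, typ, dst, group, _prov in _ATTRIBUTE_ROWS:
        snap.relationships.append(RelationshipRow(
            rid, _ET, True, _MODULE, src, dst, group, typ, _CHARACTERISTIC, _MODIFIER))

    for i, (typ, dst, group) in enumerate(_TETRALOGY_GROUPS, start=1):
        snap.relationships.append(RelationshipRow(
            str(720000000000000 + i), _ET, True, _MODULE, "86299006", dst,
            group if grouped_tetralogy else 0, typ, _CHARACTERISTIC, _MODIFIER))

    snap.validate()
    return snap


def fixture_manifest() -> str:
    """Sidecar manifest: provenance of every IS_A placement and attribute
    row (``synthetic=true`` marks fixture inventions beyond the examples)."""
    lines = ["# kind\tsource\ttarget\tprovenance\tsynthetic"]
    for sctid, _fsn, parents, prov, _status in _CONCEPTS:
        for parent in parents:
            lines.append(f"edge\t{sctid}\t{parent}\t{prov}\t"
                         f"{'true' if prov == 'synthetic' else 'false'}")
    for rid, src, typ, dst, _group, prov in _ATTRIBUTE_ROWS:
        lines.append(f"row\t{src}\t{dst}\t{prov}\t"
                     f"{'true' if prov == 'synthetic' else 'false'}")
    for typ, dst, _group in _TETRALOGY_GROUPS:
        lines.append(f"row\t86299006\t{dst}\tsynthetic\ttrue")
    return "\n".join(lines) + "\n"


def write_fixture_manifest(directory: str | Path) -> Path:
    path = Path(directory) / "fixture_manifest.tsv"
    path.write_text(fixture_manifest(), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Random RF2 taxonomies


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_concepts: int = 50
    n_attribute_types: int = 4
    max_parents: int = 3
    grouped_fraction: float = 0.5
    #: non-IS_A rows attached to each non-root concept
    rows_per_concept: int = 2

    def __post_init__(self) -> None:
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be >= 1")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if not 0.0 <= self.grouped_fraction <= 1.0:
            raise ValueError("grouped_fraction must be in [0, 1]")


def random_taxonomy(config: FixtureConfig) -> Rf2Snapshot:
    """Seeded random snapshot: an acyclic IS_A DAG under one synthetic root,
    synthetic attribute types, and a ``grouped_fraction`` share of non-IS_A
    rows carrying shared non-zero group numbers per source concept."""
    rng = random.Random(config.seed)
    snap = Rf2Snapshot()

    def add(cid: str, fsn: str) -> None:
        snap.add_concept(ConceptRow(cid, _ET, True, _MODULE, PRIMITIVE))
        snap.descriptions.append(DescriptionRow(
            cid + "011", _ET, True, _MODULE, cid, "en", FSN_TYPE, fsn, _CASE))

    root = "900001000000"
    add(root, "synthetic root")
    add(IS_A, "is a")
    attr_root = "900002000000"
    add(attr_root, "synthetic attribute root")
    for i, cid in enumerate((IS_A, attr_root)):
        snap.relationships.append(RelationshipRow(
            str(910000000000 + i), _ET, True, _MODULE, cid, root, 0, IS_A,
            _CHARACTERISTIC, _MODIFIER))

    attrs = []
    for i in range(config.n_attribute_types):
        aid = str(900003000000 + i)
        add(aid, f"synthetic attribute {i}")
        attrs.append(aid)
        snap.relationships.append(RelationshipRow(
            str(910001000000 + i), _ET, True, _MODULE, aid, attr_root, 0, IS_A,
            _CHARACTERISTIC, _MODIFIER))

    concepts = []
    rel_id = 920000000000
    for i in range(config.n_concepts):
        cid = str(900100000000 + i)
        add(cid, f"synthetic concept {i}")
        pool = concepts if concepts else [root]
        n_parents = min(len(pool), rng.randint(1, config.max_parents))
        for parent in (rng.sample(pool, n_parents) if concepts else [root]):
            rel_id += 1
            snap.relationships.append(RelationshipRow(
                str(rel_id), _ET, True, _MODULE, cid, parent, 0, IS_A,
                _CHARACTERISTIC, _MODIFIER))
        concepts.append(cid)

    for cid in concepts[1:]:
        grouped_slots: list[int] = []
        for _ in range(config.rows_per_concept):
            rel_id += 1
            if rng.random() < config.grouped_fraction:
                # pair consecutive grouped rows so groups have >= 2 members
                group = (len(grouped_slots) // 2) + 1
                grouped_slots.append(group)
            else:
                group = 0
            snap.relationships.append(RelationshipRow(
                str(rel_id), _ET, True, _MODULE, cid, rng.choice(concepts),
                group, rng.choice(attrs), _CHARACTERISTIC, _MODIFIER))

    snap.validate()
    return snap


# ---------------------------------------------------------------------------
# Random TBoxes, expressions, and interpretations (oracle harnesses)


def random_tbox(seed: int, n_names: int = 25, n_roles: int = 4,
                n_axioms: int = 40, with_disjoint: bool = False) -> TBox:
    """A seeded random TBox over digit-string names, mixing told
    subsumptions, existentials on both sides, binary conjunctions, role
    inclusions, and domain/range restrictions."""
    rng = random.Random(seed)
    names = [str(9100000 + i) for i in range(n_names)]
    roles = [str(9200000 + i) for i in range(n_roles)]
    axioms: list[TBoxAxiom] = []
    for _ in range(n_axioms):
        kind = rng.random()
        a, b, c = rng.choice(names), rng.choice(names), rng.choice(names)
        r = rng.choice(roles)
        if kind < 0.40:
            axioms.append(SubClassOf(ConceptName(a), ConceptName(b)))
        elif kind < 0.55:
            axioms.append(SubClassOf(ConceptName(a), Existential(r, ConceptName(b))))
        elif kind < 0.70:
            axioms.append(SubClassOf(Existential(r, ConceptName(a)), ConceptName(b)))
        elif kind < 0.85:
            if a == b:
                continue
            axioms.append(SubClassOf(Conjunction((ConceptName(a), ConceptName(b))),
                                     ConceptName(c)))
        elif kind < 0.90:
            r2 = rng.choice(roles)
            if r != r2:
                axioms.append(RoleInclusion(r, r2))
        elif kind < 0.95:
            axioms.append(DomainRestriction(r, ConceptName(a)))
        else:
            axioms.append(RangeRestriction(r, ConceptName(a)))
    if with_disjoint:
        a, b = rng.sample(names, 2)
        axioms.append(Disjoint(ConceptName(a), ConceptName(b)))
    return TBox(tuple(axioms))


def random_expression(rng: random.Random, names: list[str], roles: list[str],
                      depth: int = 1, allow_groups: bool = True) -> DLExpression:
    """A random CG-shaped DL expression: conjunction of concept names,
    existentials, and (optionally) role groups with name or shallow
    conjunction fillers."""
    members: list[DLExpression] = [ConceptName(rng.choice(names))
                                   for _ in range(rng.randint(1, 2))]

    def filler() -> DLExpression:
        if depth > 0 and rng.random() < 0.3:
            return conjunction_of(sorted(
                {ConceptName(rng.choice(names)) for _ in range(2)},
                key=lambda e: e.sctid))  # type: ignore[attr-defined]
        return ConceptName(rng.choice(names))

    for _ in range(rng.randint(0, 2)):
        members.append(Existential(rng.choice(roles), filler()))
    if allow_groups and rng.random() < 0.7:
        for _ in range(rng.randint(1, 2)):
            group = tuple(Existential(rng.choice(roles), filler())
                          for _ in range(rng.randint(1, 3)))
            members.append(RoleGroup(group))
    return conjunction_of(members)


def random_interpretation(rng: random.Random, names: list[str], roles: list[str],
                          size: int = 5, density: float = 0.4) -> Interpretation:
    """A random finite interpretation over the given signature."""
    domain = frozenset(range(size))
    class_ext = {n: frozenset(x for x in domain if rng.random() < density)
                 for n in names}
    role_ext = {r: frozenset((x, y) for x in domain for y in domain
                             if rng.random() < density / 2)
                for r in roles}
    return Interpretation(domain=domain, class_ext=class_ext, role_ext=role_ext)
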