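"""Build the SCTO artifact: OGMS-aligned upper scaffold + reified RF2 schema.

The ontology has three layers.  An upper-level stub tree of OGMS/BFO class
labels anchors the 19 SNOMED CT top-level hierarchies through a mapping
table (subsumption or equivalence per entry; three ambiguous hierarchies are
excluded, the linkage concept sits under the SNOMED CT Concept root only).
A reified component schema — ``SNOMED CT component`` with Concept,
Description, and Relationship subclasses, 8 object properties, and 20 data
properties — preserves every RF2 field: IS_A rows become subclass axioms,
every other relationship row becomes a Relationship individual carrying its
source/destination/type links and metadata values, and descriptions become
Description individuals.  Relationship individuals sharing a non-zero
relationshipGroup for one source concept are linked pairwise by the
symmetric ``Grouped_Relations`` property (the materialized form of the
grouping rule).  Compositional-grammar expressions translate into class
axioms in either the plain conjunction-of-restrictions pattern or the
reified pattern with ``Grouped_Relations exactly 1`` linkages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import yaml

from .cg import CGAttribute, CGExpression, ConceptRef, ConcreteValue
from .rf2 import IS_A, FULLY_DEFINED, Rf2Snapshot, TaxonomyIndex, taxonomy_index


class SctoError(ValueError):
    """Invalid mapping table, missing references, or malformed input."""


# ---------------------------------------------------------------------------
# OWL class expressions (the subset the listings use)


class ClassExpr:
    __slots__ = ()


@dataclass(frozen=True)
class ClassRef(ClassExpr):
    iri: str


@dataclass(frozen=True)
class And(ClassExpr):
    members: tuple[ClassExpr, ...]


@dataclass(frozen=True)
class Some(ClassExpr):
    prop: str
    filler: ClassExpr


@dataclass(frozen=True)
class Only(ClassExpr):
    prop: str
    filler: ClassExpr


@dataclass(frozen=True)
class Exactly(ClassExpr):
    n: int
    prop: str
    filler: ClassExpr


@dataclass(frozen=True)
class DataHasValue(ClassExpr):
    prop: str
    value: str
    datatype: str = "xsd:string"


@dataclass(frozen=True)
class DataOnly(ClassExpr):
    """``p only {"value"}`` — a universal restriction to one literal, as the
    N-ary reification pattern uses for relationship metadata."""

    prop: str
    value: str
    datatype: str = "xsd:string"


# ---------------------------------------------------------------------------
# Ontology container


@dataclass(frozen=True)
class OntClass:
    iri: str
    label: str
    definition: str = ""


@dataclass(frozen=True)
class ObjectProperty:
    name: str
    definition: str
    domain: str
    range: str
    inverse_of: str | None = None
    characteristics: tuple[str, ...] = ()


@dataclass(frozen=True)
class DataProperty:
    name: str
    definition: str
    domain: str
    range_datatype: str
    functional: bool = True


@dataclass(frozen=True)
class SubClassOfAxiom:
    subject: str
    expr: ClassExpr


@dataclass(frozen=True)
class EquivalentToAxiom:
    subject: str
    expr: ClassExpr


@dataclass(frozen=True)
class DisjointClassesAxiom:
    members: tuple[str, ...]


ClassAxiom = SubClassOfAxiom | EquivalentToAxiom | DisjointClassesAxiom


@dataclass(frozen=True)
class Individual:
    iri: str
    types: tuple[str, ...]
    object_assertions: tuple[tuple[str, str], ...] = ()
    data_assertions: tuple[tuple[str, str, str], ...] = ()  # (prop, lexical, datatype)


@dataclass
class Ontology:
    """The SCTO artifact, serializable by :mod:`sctoforge.owl`."""

    iri_base: str = "https://local.invalid/scto"
    classes: dict[str, OntClass] = field(default_factory=dict)
    object_properties: dict[str, ObjectProperty] = field(default_factory=dict)
    data_properties: dict[str, DataProperty] = field(default_factory=dict)
    class_axioms: list[ClassAxiom] = field(default_factory=list)
    individuals: dict[str, Individual] = field(default_factory=dict)
    grouped_relations: set[tuple[str, str]] = field(default_factory=set)
    rules: list[str] = field(default_factory=list)

    def add_class(self, iri: str, label: str, definition: str = "") -> None:
        existing = self.classes.get(iri)
        if existing is None or (not existing.definition and definition):
            self.classes[iri] = OntClass(iri, label, definition)

    def add_axiom(self, axiom: ClassAxiom) -> None:
        if axiom not in self.class_axioms:
            self.class_axioms.append(axiom)

    def has_class(self, iri: str) -> bool:
        return iri in self.classes

    def annotation_count(self) -> int:
        """Annotation assertions: one label per class/property plus one
        textual definition where present."""
        n = 0
        for c in self.classes.values():
            n += 1 + (1 if c.definition else 0)
        for p in self.object_properties.values():
            n += 1 + (1 if p.definition else 0)
        for p in self.data_properties.values():
            n += 1 + (1 if p.definition else 0)
        return n

    def subclass_edges(self) -> list[tuple[str, str]]:
        """Named subclass edges (subject, direct named superclass)."""
        edges = []
        for ax in self.class_axioms:
            if isinstance(ax, SubClassOfAxiom) and isinstance(ax.expr, ClassRef):
                edges.append((ax.subject, ax.expr.iri))
        return edges

    def grouped_pairs(self) -> set[frozenset]:
        return {frozenset(p) for p in self.grouped_relations}


def concept_iri(sctid: str) -> str:
    return f"SCTO_{sctid}"


def _slug(label: str) -> str:
    return re.sub(r"\W+", "_", label).strip("_")


# ---------------------------------------------------------------------------
# Mapping table


MappingKind = Literal["subsumption", "equivalence", "child-of-root", "excluded"]


@dataclass(frozen=True)
class MappingEntry:
    sct_id: str
    sct_label: str
    upper_class: str  # label of an OGMS/BFO stub class ('' for child-of-root/excluded)
    kind: MappingKind


ROOT_CONCEPT = "138875005"

#: upper-level stub tree: (label, parent label or None).  Labels only; the
#: real OGMS/BFO artifacts are not imported.
UPPER_STUBS: tuple[tuple[str, str | None], ...] = (
    ("entity", None),
    ("continuant", "entity"),
    ("occurrent", "entity"),
    ("material entity", "continuant"),
    ("immaterial entity", "continuant"),
    ("site", "immaterial entity"),
    ("quality", "continuant"),
    ("disposition", "continuant"),
    ("information content entity", "continuant"),
    ("data item", "information content entity"),
    ("object", "material entity"),
    ("anatomical entity", "material entity"),
    ("organism", "material entity"),
    ("specimen", "material entity"),
    ("drug product", "material entity"),
    ("disorder", "material entity"),
    ("process", "occurrent"),
    ("planned process", "process"),
    ("pathological process", "process"),
)

#: default mapping: the 19 top-level hierarchies plus the root row
#: "SNOMED CT Concept subClassOf entity" — 17 mappings in total, 14 of them
#: subsumptions (82.35%), 2 equivalences, 1 child-of-root, 3 excluded.
DEFAULT_MAPPING: tuple[MappingEntry, ...] = (
    MappingEntry(ROOT_CONCEPT, "SNOMED CT Concept", "entity", "subsumption"),
    MappingEntry("404684003", "clinical finding", "disorder", "subsumption"),
    MappingEntry("71388002", "procedure", "planned process", "subsumption"),
    MappingEntry("363787002", "observable entity", "quality", "subsumption"),
    MappingEntry("123037004", "body structure", "anatomical entity", "subsumption"),
    MappingEntry("410607006", "organism", "organism", "equivalence"),
    MappingEntry("105590001", "substance", "material entity", "subsumption"),
    MappingEntry("373873005", "pharmaceutical / biologic product", "drug product", "subsumption"),
    MappingEntry("123038009", "specimen", "specimen", "equivalence"),
    MappingEntry("260787004", "physical object", "object", "subsumption"),
    MappingEntry("78621006", "physical force", "process", "subsumption"),
    MappingEntry("272379006", "event", "process", "subsumption"),
    MappingEntry("308916002", "environment or geographical location", "site", "subsumption"),
    MappingEntry("254291000", "staging and scales", "information content entity", "subsumption"),
    MappingEntry("419891008", "record artifact", "information content entity", "subsumption"),
    MappingEntry("362981000", "qualifier value", "data item", "subsumption"),
    MappingEntry("106237007", "linkage concept", "", "child-of-root"),
    MappingEntry("48176007", "social context", "", "excluded"),
    MappingEntry("243796009", "situation with explicit context", "", "excluded"),
    MappingEntry("370115009", "special concept", "", "excluded"),
)

#: the printed disjointness list: 15 of the 16 modeled hierarchies (a class
#: cannot be a subclass of more than one top-level hierarchy).
DISJOINT_HIERARCHIES: tuple[str, ...] = (
    "373873005", "78621006", "106237007", "308916002", "362981000",
    "363787002", "419891008", "71388002", "272379006", "123038009",
    "105590001", "254291000", "260787004", "404684003", "410607006",
)


def mapping_stats(mapping: Sequence[MappingEntry]) -> dict[str, float | int]:
    """Counts and percentage shares over the mapped (non-excluded) rows."""
    kinds = {"subsumption": 0, "equivalence": 0, "child-of-root": 0, "excluded": 0}
    for e in mapping:
        kinds[e.kind] += 1
    mapped = kinds["subsumption"] + kinds["equivalence"] + kinds["child-of-root"]
    top_level = [e for e in mapping if e.sct_id != ROOT_CONCEPT]
    return {
        "top_level_concepts": len(top_level),
        "modeled": len([e for e in top_level if e.kind != "excluded"]),
        "excluded": kinds["excluded"],
        "mappings": mapped,
        "subsumption": kinds["subsumption"],
        "equivalence": kinds["equivalence"],
        "child_of_root": kinds["child-of-root"],
        "subsumption_share": round(100.0 * kinds["subsumption"] / mapped, 2) if mapped else 0.0,
        "equivalence_share": round(100.0 * kinds["equivalence"] / mapped, 2) if mapped else 0.0,
        "no_equivalence_share": round(100.0 * kinds["child-of-root"] / mapped, 2) if mapped else 0.0,
    }


def validate_mapping(mapping: Sequence[MappingEntry]) -> None:
    ids = [e.sct_id for e in mapping]
    if len(ids) != len(set(ids)):
        raise SctoError("mapping table has duplicate SCT ids")
    top_level = [e for e in mapping if e.sct_id != ROOT_CONCEPT]
    if len(top_level) != 19:
        raise SctoError(f"mapping must cover the 19 top-level concepts, got {len(top_level)}")
    stats = mapping_stats(mapping)
    if stats["excluded"] != 3:
        raise SctoError(f"exactly 3 top-level concepts are excluded, got {stats['excluded']}")
    if (stats["subsumption"], stats["equivalence"], stats["child_of_root"]) != (14, 2, 1):
        raise SctoError(
            "mapping kinds must split 14 subsumption / 2 equivalence / 1 child-of-root, got "
            f"{stats['subsumption']}/{stats['equivalence']}/{stats['child_of_root']}")
    stub_labels = {label for label, _parent in UPPER_STUBS}
    for e in mapping:
        if e.kind in ("subsumption", "equivalence") and e.upper_class not in stub_labels:
            raise SctoError(f"{e.sct_label}: unknown upper-level class {e.upper_class!r}")


# ---------------------------------------------------------------------------
# Schema constants

COMPONENT = "SCTO_Component"
CONCEPT_CLASS = concept_iri(ROOT_CONCEPT)  # SNOMED CT Concept
DESCRIPTION_CLASS = "SCTO_Description"
RELATIONSHIP_CLASS = "SCTO_Relationship"

GROUPING_RULE = (
    "Relationship_relationshipGroup(?r1, ?n1), "
    "Relationship_relationshipGroup(?r2, ?n2), "
    "Relationship_sourceId(?r1, ?c), Relationship_sourceId(?r2, ?c), "
    "equal(?n1, ?n2) -> Grouped_Relations(?r1, ?r2)"
)

_OBJECT_PROPERTIES: tuple[ObjectProperty, ...] = (
    ObjectProperty("Has_description", "Determines a description for a class.",
                   CONCEPT_CLASS, DESCRIPTION_CLASS, inverse_of="IsDescriptionOf"),
    ObjectProperty("IsDescriptionOf", "Is the inverse of Has_description.",
                   DESCRIPTION_CLASS, CONCEPT_CLASS, inverse_of="Has_description"),
    ObjectProperty("Relationship_destinationId",
                   "Identifies the class that is the destination of the relationship.",
                   RELATIONSHIP_CLASS, CONCEPT_CLASS, inverse_of="IsDestinationOf"),
    ObjectProperty("Relationship_sourceId",
                   "Identifies the source concept of the relationship.",
                   RELATIONSHIP_CLASS, CONCEPT_CLASS, inverse_of="IsSourceOf"),
    ObjectProperty("Relationship_typeId",
                   "A concept enumeration value that identifies the semantic type "
                   "of the relationship; a subtype of the concept model attribute.",
                   RELATIONSHIP_CLASS, concept_iri("106237007")),
    ObjectProperty("IsSourceOf",
                   "Determines the source of a relationship; inverse of Relationship_sourceId.",
                   CONCEPT_CLASS, RELATIONSHIP_CLASS, inverse_of="Relationship_sourceId"),
    ObjectProperty("IsDestinationOf",
                   "Determines the destination of a relationship; inverse of "
                   "Relationship_destinationId.",
                   CONCEPT_CLASS, RELATIONSHIP_CLASS, inverse_of="Relationship_destinationId"),
    ObjectProperty("Grouped_Relations",
                   "Used to explicitly determine the grouped relationships.",
                   RELATIONSHIP_CLASS, RELATIONSHIP_CLASS, characteristics=("Symmetric",)),
)

# 20 data properties: 5 Concept + 8 Description + 7 Relationship columns.
_DATA_PROPERTIES: tuple[DataProperty, ...] = (
    DataProperty("Concept_Id", "The unique SNOMED CT identifier for this concept.",
                 CONCEPT_CLASS, "xsd:string"),
    DataProperty("Concept_effectiveTime", "Release date at which the concept state applies.",
                 CONCEPT_CLASS, "xsd:string"),
    DataProperty("Concept_active", "Whether the concept is active in the release.",
                 CONCEPT_CLASS, "xsd:boolean"),
    DataProperty("Concept_moduleId", "Module containing the concept.",
                 CONCEPT_CLASS, "xsd:string"),
    DataProperty("Concept_definitionStatusId",
                 "Whether the concept is primitive or fully defined.",
                 CONCEPT_CLASS, "xsd:string"),
    DataProperty("Description_id", "The unique identifier of this description.",
                 DESCRIPTION_CLASS, "xsd:string"),
    DataProperty("Description_effectiveTime",
                 "Release date at which the description state applies.",
                 DESCRIPTION_CLASS, "xsd:string"),
    DataProperty("Description_active", "Whether the description is active.",
                 DESCRIPTION_CLASS, "xsd:boolean"),
    DataProperty("Description_moduleId", "Module containing the description.",
                 DESCRIPTION_CLASS, "xsd:string"),
    DataProperty("Description_languageCode", "Language of the description term.",
                 DESCRIPTION_CLASS, "xsd:string"),
    DataProperty("Description_typeId",
                 "Identifies whether the description is an FSN, synonym, or other type.",
                 DESCRIPTION_CLASS, "xsd:string"),
    DataProperty("Description_term",
                 "The description's text value, represented in UTF-8 encoding.",
                 DESCRIPTION_CLASS, "xsd:string"),
    DataProperty("Description_caseSignificanceId", "Case significance of the term.",
                 DESCRIPTION_CLASS, "xsd:string"),
    DataProperty("Relationship_id", "The unique identifier of this relationship.",
                 RELATIONSHIP_CLASS, "xsd:string"),
    DataProperty("Relationship_effectiveTime",
                 "Release date at which the relationship state applies.",
                 RELATIONSHIP_CLASS, "xsd:string"),
    DataProperty("Relationship_active",
                 "Specifies whether the relationship's state is active or inactive.",
                 RELATIONSHIP_CLASS, "xsd:boolean"),
    DataProperty("Relationship_moduleId", "Module containing the relationship.",
                 RELATIONSHIP_CLASS, "xsd:string"),
    DataProperty("Relationship_relationshipGroup",
                 "Groups together relationship versions that are part of a "
                 "logically associated relationship group.",
                 RELATIONSHIP_CLASS, "xsd:integer"),
    DataProperty("Relationship_characteristicTypeId",
                 "A concept enumeration value that identifies the characteristic "
                 "type of the relationship.",
                 RELATIONSHIP_CLASS, "xsd:string"),
    DataProperty("Relationship_modifierId", "Modifier of the relationship.",
                 RELATIONSHIP_CLASS, "xsd:string"),
)


def build_scaffold(mapping: Sequence[MappingEntry] = DEFAULT_MAPPING,
                   iri_base: str = "https://local.invalid/scto") -> Ontology:
    """A fresh SCTO scaffold (no RF2 content yet)."""
    validate_mapping(mapping)
    ont = Ontology(iri_base=iri_base)

    for label, parent in UPPER_STUBS:
        iri = "UPPER_" + _slug(label)
        ont.add_class(iri, label, f"Upper-level stub class for {label}.")
        if parent is not None:
            ont.add_axiom(SubClassOfAxiom(iri, ClassRef("UPPER_" + _slug(parent))))

    ont.add_class(COMPONENT, "SNOMED CT component",
                  "Root of the reified component schema: concepts, descriptions, "
                  "and relationships.")
    ont.add_class(DESCRIPTION_CLASS, "SNOMED CT Description",
                  "A reified row of the RF2 description table.")
    ont.add_class(RELATIONSHIP_CLASS, "SNOMED CT Relationship",
                  "A reified row of the RF2 relationship table.")
    ont.add_axiom(SubClassOfAxiom(DESCRIPTION_CLASS, ClassRef(COMPONENT)))
    ont.add_axiom(SubClassOfAxiom(RELATIONSHIP_CLASS, ClassRef(COMPONENT)))

    for entry in mapping:
        if entry.kind == "excluded":
            continue
        iri = concept_iri(entry.sct_id)
        ont.add_class(iri, entry.sct_label,
                      f"SNOMED CT top-level hierarchy: {entry.sct_label}."
                      if entry.sct_id != ROOT_CONCEPT
                      else "The root of the SNOMED CT concept hierarchy.")
        if entry.sct_id == ROOT_CONCEPT:
            ont.add_axiom(SubClassOfAxiom(iri, ClassRef(COMPONENT)))
            ont.add_axiom(SubClassOfAxiom(iri, ClassRef("UPPER_" + _slug(entry.upper_class))))
            continue
        ont.add_axiom(SubClassOfAxiom(iri, ClassRef(CONCEPT_CLASS)))
        if entry.kind == "subsumption":
            ont.add_axiom(SubClassOfAxiom(iri, ClassRef("UPPER_" + _slug(entry.upper_class))))
        elif entry.kind == "equivalence":
            ont.add_axiom(EquivalentToAxiom(iri, ClassRef("UPPER_" + _slug(entry.upper_class))))
        # child-of-root: subclass of SNOMED CT Concept only

    for prop in _OBJECT_PROPERTIES:
        ont.object_properties[prop.name] = prop
    for dprop in _DATA_PROPERTIES:
        ont.data_properties[dprop.name] = dprop

    ont.add_axiom(DisjointClassesAxiom(
        tuple(concept_iri(s) for s in DISJOINT_HIERARCHIES)))
    ont.rules.append(GROUPING_RULE)
    return ont


# ---------------------------------------------------------------------------
# Reification of RF2 content


def _xsd_bool(v: bool) -> str:
    return "true" if v else "false"


def reify(snapshot: Rf2Snapshot, ont: Ontology) -> Ontology:
    """Fold a snapshot into the ontology (deterministic and idempotent).

    Concepts become classes; active IS_A rows become subclass axioms (never
    object-property assertions); every description and every non-IS_A
    relationship row becomes an individual carrying the preserved RF2 fields;
    a fully defined concept additionally receives an equivalence over its
    parents and reified group restrictions.
    """
    snapshot.validate()
    missing = [r.id for r in snapshot.relationships
               if r.sourceId not in snapshot.concepts
               or r.destinationId not in snapshot.concepts]
    if missing:
        raise SctoError(f"dangling relationship references: {missing}")

    for cid, concept in sorted(snapshot.concepts.items()):
        iri = concept_iri(cid)
        label = snapshot.fsn(cid) or cid
        ont.add_class(iri, label, f"SNOMED CT concept {cid} ({label}).")
        if cid != ROOT_CONCEPT:
            ont.add_class(CONCEPT_CLASS, "SNOMED CT Concept")

    parents: dict[str, list[str]] = {}
    by_source: dict[str, dict[int, list]] = {}
    for r in sorted(snapshot.relationships, key=lambda r: r.id):
        if not r.active:
            continue
        if r.typeId == IS_A:
            parents.setdefault(r.sourceId, []).append(r.destinationId)
            ont.add_axiom(SubClassOfAxiom(concept_iri(r.sourceId),
                                          ClassRef(concept_iri(r.destinationId))))
        else:
            by_source.setdefault(r.sourceId, {}).setdefault(r.relationshipGroup, []).append(r)

    for d in sorted(snapshot.descriptions, key=lambda d: d.id):
        iri = f"SCTO_D_{d.id}"
        ont.individuals[iri] = Individual(
            iri, (DESCRIPTION_CLASS,),
            object_assertions=(("IsDescriptionOf", concept_iri(d.conceptId)),),
            data_assertions=(
                ("Description_id", d.id, "xsd:string"),
                ("Description_effectiveTime", d.effectiveTime, "xsd:string"),
                ("Description_active", _xsd_bool(d.active), "xsd:boolean"),
                ("Description_moduleId", d.moduleId, "xsd:string"),
                ("Description_languageCode", d.languageCode, "xsd:string"),
                ("Description_typeId", d.typeId, "xsd:string"),
                ("Description_term", d.term, "xsd:string"),
                ("Description_caseSignificanceId", d.caseSignificanceId, "xsd:string"),
            ))

    for r in sorted(snapshot.relationships, key=lambda r: r.id):
        if r.typeId == IS_A:
            continue
        iri = f"SCTO_R_{r.id}"
        ont.individuals[iri] = Individual(
            iri, (RELATIONSHIP_CLASS,),
            object_assertions=(
                ("Relationship_sourceId", concept_iri(r.sourceId)),
                ("Relationship_destinationId", concept_iri(r.destinationId)),
                ("Relationship_typeId", concept_iri(r.typeId)),
            ),
            data_assertions=(
                ("Relationship_id", r.id, "xsd:string"),
                ("Relationship_effectiveTime", r.effectiveTime, "xsd:string"),
                ("Relationship_active", _xsd_bool(r.active), "xsd:boolean"),
                ("Relationship_moduleId", r.moduleId, "xsd:string"),
                ("Relationship_relationshipGroup", str(r.relationshipGroup), "xsd:integer"),
                ("Relationship_characteristicTypeId", r.characteristicTypeId, "xsd:string"),
                ("Relationship_modifierId", r.modifierId, "xsd:string"),
            ))

    # fully defined concepts: equivalence over parents + reified groups
    for cid in sorted(snapshot.concepts):
        concept = snapshot.concepts[cid]
        if concept.definitionStatusId != FULLY_DEFINED:
            continue
        members: list[ClassExpr] = [ClassRef(concept_iri(p))
                                    for p in sorted(parents.get(cid, []))]
        groups = by_source.get(cid, {})
        for gnum in sorted(groups):
            attrs = [(concept_iri(r.typeId), ClassRef(concept_iri(r.destinationId)))
                     for r in sorted(groups[gnum], key=lambda r: r.id)]
            if gnum == 0:
                members.extend(_is_source_of(t, v) for t, v in attrs)
            else:
                members.append(_reified_group(attrs))
        if members:
            ont.add_axiom(EquivalentToAxiom(
                concept_iri(cid),
                members[0] if len(members) == 1 else And(tuple(members))))
    return ont


def _restriction(type_iri: str, value: ClassExpr) -> ClassExpr:
    return And((Some("Relationship_destinationId", value),
                Some("Relationship_typeId", ClassRef(type_iri))))


def _is_source_of(type_iri: str, value: ClassExpr) -> ClassExpr:
    return Some("IsSourceOf", _restriction(type_iri, value))


def _reified_group(attrs: list[tuple[str, ClassExpr]]) -> ClassExpr:
    """One group block: the first restriction linked to the rest by
    ``Grouped_Relations exactly 1`` (the closed-skull listing pattern)."""
    head = _restriction(*attrs[0])
    rest = [Exactly(1, "Grouped_Relations", _restriction(t, v)) for t, v in attrs[1:]]
    return Some("IsSourceOf", head if not rest else And((head, *rest)))


def reify_nary(snapshot: Rf2Snapshot, ont: Ontology) -> Ontology:
    """Alternate N-ary reification: model each non-IS_A row as a class.

    Every active attribute row becomes a subclass of its relationship-type
    concept holding a ``has_location`` link to the destination and universal
    restrictions pinning the row's metadata to single literals; the source
    concept is restricted to that row class through a per-attribute
    ``has_<type>`` property.  The relationship-hierarchy shape of the
    terminology is preserved, at the cost of the known limitations of N-ary
    modelling — the individual-based schema (:func:`reify`) is the default.
    """
    snapshot.validate()
    if "has_location" not in ont.object_properties:
        ont.object_properties["has_location"] = ObjectProperty(
            "has_location", "Destination of a reified N-ary relationship class.",
            concept_iri("410662002"), concept_iri("123037004"),
            characteristics=("Functional",))
    for name, dt in (("has_relationshipId", "xsd:string"),
                     ("has_moduleId", "xsd:string"),
                     ("has_typeId", "xsd:string"),
                     ("has_characteristicTypeId", "xsd:string"),
                     ("has_modifierId", "xsd:string"),
                     ("has_relationshipGroup", "xsd:integer")):
        if name not in ont.data_properties:
            ont.data_properties[name] = DataProperty(
                name, f"Preserved RF2 field of a reified N-ary relationship ({name}).",
                concept_iri("410662002"), dt)
    for r in sorted(snapshot.relationships, key=lambda r: r.id):
        if not r.active or r.typeId == IS_A:
            continue
        type_label = snapshot.fsn(r.typeId) or r.typeId
        prop = "has_" + _slug(type_label)
        if prop not in ont.object_properties:
            ont.object_properties[prop] = ObjectProperty(
                prop, f"N-ary link to a reified {type_label} relationship.",
                concept_iri(r.sourceId), concept_iri(r.typeId))
        row_iri = f"SCTO_N_{r.id}"
        ont.add_class(row_iri, type_label,
                      f"Reified N-ary relationship row {r.id} ({type_label}).")
        ont.add_axiom(SubClassOfAxiom(row_iri, And((
            ClassRef(concept_iri(r.typeId)),
            Some("has_location", ClassRef(concept_iri(r.destinationId))),
            DataOnly("has_relationshipId", r.id),
            DataOnly("has_moduleId", r.moduleId),
            DataOnly("has_typeId", r.typeId),
            DataOnly("has_characteristicTypeId", r.characteristicTypeId),
            DataOnly("has_modifierId", r.modifierId),
            DataOnly("has_relationshipGroup", str(r.relationshipGroup), "xsd:integer"),
        ))))
        ont.add_axiom(SubClassOfAxiom(
            concept_iri(r.sourceId), Only(prop, ClassRef(row_iri))))
    return ont


def materialize_groups(ont: Ontology) -> Ontology:
    """Add symmetric ``Grouped_Relations`` assertions for every pair of
    distinct Relationship individuals sharing a source concept and an equal
    non-zero relationshipGroup; group 0 never links."""
    buckets: dict[tuple[str, str], list[str]] = {}
    for iri, ind in ont.individuals.items():
        if RELATIONSHIP_CLASS not in ind.types:
            continue
        source = dict(ind.object_assertions).get("Relationship_sourceId")
        group = dict((p, v) for p, v, _dt in ind.data_assertions).get(
            "Relationship_relationshipGroup", "0")
        if source is None or group == "0":
            continue
        buckets.setdefault((source, group), []).append(iri)
    for members in buckets.values():
        for a in members:
            for b in members:
                if a != b:
                    ont.grouped_relations.add((a, b))
    return ont


# ---------------------------------------------------------------------------
# Expressions -> ontology axioms


def _check_known(ont: Ontology, sctid: str) -> str:
    iri = concept_iri(sctid)
    if not ont.has_class(iri):
        raise SctoError(f"unknown SCTID {sctid}: no class {iri} in the ontology")
    return iri


_CONCRETE_PROP = DataProperty(
    "Relationship_concreteValue",
    "Concrete (primitive-typed) attribute value of a reified relationship.",
    RELATIONSHIP_CLASS, "xsd:string")


def _value_expr(ont: Ontology, value, pattern: str) -> ClassExpr:
    if isinstance(value, ConceptRef):
        return ClassRef(_check_known(ont, value.sctid))
    if isinstance(value, ConcreteValue):
        if _CONCRETE_PROP.name not in ont.data_properties:
            ont.data_properties[_CONCRETE_PROP.name] = _CONCRETE_PROP
        if value.kind == "numeric":
            return DataHasValue(_CONCRETE_PROP.name, str(value.numeric_value), "xsd:decimal")
        return DataHasValue(_CONCRETE_PROP.name, str(value.text_value), "xsd:string")
    return _expression_class_expr(ont, value, pattern)


def _attr_expr(ont: Ontology, attr: CGAttribute, pattern: str) -> ClassExpr:
    type_iri = _check_known(ont, attr.name.sctid)
    return _is_source_of(type_iri, _value_expr(ont, attr.value, pattern))


def _expression_class_expr(ont: Ontology, expr: CGExpression, pattern: str) -> ClassExpr:
    members: list[ClassExpr] = [ClassRef(_check_known(ont, f.sctid)) for f in expr.focus]
    members += [_attr_expr(ont, a, pattern) for a in expr.ungrouped]
    for group in expr.groups:
        if pattern == "reified":
            attrs = [(_check_known(ont, a.name.sctid), _value_expr(ont, a.value, pattern))
                     for a in group]
            members.append(_reified_group(attrs))
        else:
            members.extend(_attr_expr(ont, a, pattern) for a in group)
    return members[0] if len(members) == 1 else And(tuple(members))


def expression_to_axioms(expr: CGExpression, pattern: Literal["plain", "reified"],
                         ont: Ontology, new_class_label: str) -> Ontology:
    """Add a class axiom for a compositional-grammar expression.

    ``plain`` emits the direct conjunction-plus-IsSourceOf-restrictions
    pattern of the diabetes listing; ``reified`` wraps each attribute
    group's restrictions with ``Grouped_Relations exactly 1`` linkages as in
    the closed-skull listing.  The axiom kind follows the expression status.
    """
    ce = _expression_class_expr(ont, expr, pattern)
    iri = "SCTO_EXP_" + _slug(new_class_label)
    ont.add_class(iri, new_class_label, f"Post-coordinated expression: {new_class_label}.")
    if expr.status == "subtype":
        ont.add_axiom(SubClassOfAxiom(iri, ce))
    else:
        ont.add_axiom(EquivalentToAxiom(iri, ce))
    return ont


# ---------------------------------------------------------------------------
# SCM (concept model) validation


@dataclass(frozen=True)
class SCMRule:
    """One branch of the concept model: which hierarchy may carry which
    attribute, with which value hierarchies; descendants of a permitted
    value are also permitted."""

    domain_hierarchy: str
    attribute: str
    permitted_value_hierarchies: tuple[str, ...]
    groupable: bool = True


DEFAULT_SCM_RULES: tuple[SCMRule, ...] = (
    # clinical finding: finding site takes (acquired) body structures
    SCMRule("404684003", "363698007", ("91723000", "280115004")),
    SCMRule("404684003", "116676008", ("49755003",)),
    SCMRule("404684003", "246456000", ("362981000",), groupable=False),
    SCMRule("404684003", "246075003", ("410607006", "105590001")),
)


@dataclass(frozen=True)
class SCMViolation:
    source: tuple[str, ...]
    attribute: str
    value: str | None
    message: str


def _applications(expr: CGExpression) -> list[tuple[tuple[str, ...], str, str | None]]:
    """(source concepts, attribute, value concept) triples, recursively."""
    out = []
    sources = tuple(f.sctid for f in expr.focus)
    for attr in expr.attributes():
        value = attr.value
        if isinstance(value, ConceptRef):
            out.append((sources, attr.name.sctid, value.sctid))
        elif isinstance(value, ConcreteValue):
            out.append((sources, attr.name.sctid, None))
        else:
            for focus in value.focus:
                out.append((sources, attr.name.sctid, focus.sctid))
            out.extend(_applications(value))
    return out


def scm_validate(target: CGExpression | Rf2Snapshot, rules: Sequence[SCMRule],
                 taxonomy: TaxonomyIndex) -> list[SCMViolation]:
    """Check attribute applications against the concept-model rule table.

    Attributes without any rule are not judged.  A violation is recorded
    when no rule for the attribute covers the source concept's hierarchy,
    or when the value is not a descendant-or-self of any permitted value
    hierarchy of a covering rule.
    """
    if isinstance(target, Rf2Snapshot):
        apps = [((r.sourceId,), r.typeId, r.destinationId)
                for r in target.relationships if r.active and r.typeId != IS_A]
    else:
        apps = _applications(target)

    violations: list[SCMViolation] = []
    by_attr: dict[str, list[SCMRule]] = {}
    for rule in rules:
        by_attr.setdefault(rule.attribute, []).append(rule)

    for sources, attribute, value in apps:
        candidates = by_attr.get(attribute)
        if not candidates:
            continue
        covering = [rule for rule in candidates
                    if any(taxonomy.is_a_or_self(s, rule.domain_hierarchy) for s in sources)]
        if not covering:
            violations.append(SCMViolation(
                sources, attribute, value,
                f"attribute {attribute} does not apply to {'/'.join(sources)}: "
                f"source is outside the permitted domain hierarchies"))
            continue
        if value is None:
            continue  # concrete values are not hierarchy-checked
        if not any(taxonomy.is_a_or_self(value, permitted)
                   for rule in covering for permitted in rule.permitted_value_hierarchies):
            violations.append(SCMViolation(
                sources, attribute, value,
                f"value {value} is not a descendant-or-self of any permitted "
                f"value hierarchy for attribute {attribute}"))
    return violations


# ---------------------------------------------------------------------------
# Config I/O


def load_mapping(path: str | Path) -> tuple[MappingEntry, ...]:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    entries = tuple(
        MappingEntry(str(e["sct_id"]), e["sct_label"], e.get("upper_class", ""), e["kind"])
        for e in data["mapping"])
    validate_mapping(entries)
    return entries


def dump_mapping(mapping: Sequence[MappingEntry], path: str | Path) -> None:
    data = {"mapping": [
        {"sct_id": e.sct_id, "sct_label": e.sct_label,
         "upper_class": e.upper_class, "kind": e.kind} for e in mapping]}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def load_scm_rules(path: str | Path) -> tuple[SCMRule, ...]:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return tuple(
        SCMRule(str(r["domain"]), str(r["attribute"]),
                tuple(str(v) for v in r["values"]), bool(r.get("groupable", True)))
        for r in data["scm_rules"])


def dump_scm_rules(rules: Sequence[SCMRule], path: str | Path) -> None:
    data = {"scm_rules": [
        {"domain": r.domain_hierarchy, "attribute": r.attribute,
         "values": list(r.permitted_value_hierarchies), "groupable": r.groupable}
        for r in rules]}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
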