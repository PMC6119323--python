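"""RF2 snapshot I/O and the IS_A taxonomy index.

SNOMED CT ships as tab-separated Release Format 2 (RF2) files.  This module
is the only gateway between those files and the in-memory model: it reads the
three snapshot tables (Concept, Description, Relationship), validates
referential integrity, writes them back byte-deterministically, and builds a
transitive-closure index over the active ``116680003 |is a|`` rows.

SCT identifiers are kept as strings end to end: SCTIDs can exceed the 53-bit
range where floats stay exact, and downstream canonical ordering is
lexicographic on the digit string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

# Well-known SCTIDs used throughout the package.
IS_A = "116680003"
PRIMITIVE = "900000000000074008"
FULLY_DEFINED = "900000000000073002"
DEFINITION_STATUS_IDS = frozenset({PRIMITIVE, FULLY_DEFINED})

FSN_TYPE = "900000000000003001"
SYNONYM_TYPE = "900000000000013009"

CONCEPT_COLUMNS = ("id", "effectiveTime", "active", "moduleId", "definitionStatusId")
DESCRIPTION_COLUMNS = (
    "id", "effectiveTime", "active", "moduleId", "conceptId",
    "languageCode", "typeId", "term", "caseSignificanceId",
)
RELATIONSHIP_COLUMNS = (
    "id", "effectiveTime", "active", "moduleId", "sourceId", "destinationId",
    "relationshipGroup", "typeId", "characteristicTypeId", "modifierId",
)

CONCEPT_FILE = "sct2_Concept_Snapshot.txt"
DESCRIPTION_FILE = "sct2_Description_Snapshot.txt"
RELATIONSHIP_FILE = "sct2_Relationship_Snapshot.txt"


class Rf2Error(ValueError):
    """Malformed RF2 content (bad row shape, broken references, cycles)."""


def _require_sctid(value: str, what: str, line: int | None = None) -> str:
    if not value or not value.isdigit():
        where = f" (line {line})" if line is not None else ""
        raise Rf2Error(f"{what} must be a non-empty digit string, got {value!r}{where}")
    return value


@dataclass(frozen=True)
class ConceptRow:
    id: str
    effectiveTime: str
    active: bool
    moduleId: str
    definitionStatusId: str

    def __post_init__(self) -> None:
        _require_sctid(self.id, "concept id")
        if self.definitionStatusId not in DEFINITION_STATUS_IDS:
            raise Rf2Error(
                f"definitionStatusId of {self.id} must be primitive "
                f"({PRIMITIVE}) or fully defined ({FULLY_DEFINED}), "
                f"got {self.definitionStatusId!r}"
            )


@dataclass(frozen=True)
class DescriptionRow:
    id: str
    effectiveTime: str
    active: bool
    moduleId: str
    conceptId: str
    languageCode: str
    typeId: str
    term: str
    caseSignificanceId: str

    def __post_init__(self) -> None:
        _require_sctid(self.id, "description id")
        _require_sctid(self.conceptId, "description conceptId")


@dataclass(frozen=True)
class RelationshipRow:
    id: str
    effectiveTime: str
    active: bool
    moduleId: str
    sourceId: str
    destinationId: str
    relationshipGroup: int
    typeId: str
    characteristicTypeId: str
    modifierId: str

    def __post_init__(self) -> None:
        _require_sctid(self.id, "relationship id")
        _require_sctid(self.sourceId, "sourceId")
        _require_sctid(self.destinationId, "destinationId")
        if self.relationshipGroup < 0:
            raise Rf2Error(f"relationshipGroup must be >= 0, got {self.relationshipGroup}")
        # IS_A has a special nature: it is always ungrouped.
        if self.typeId == IS_A and self.relationshipGroup != 0:
            raise Rf2Error(
                f"relationship {self.id}: IS_A rows are always ungrouped "
                f"(relationshipGroup = 0), got group {self.relationshipGroup}"
            )


@dataclass
class Rf2Snapshot:
    """In-memory image of one RF2 snapshot (all three tables)."""

    concepts: dict[str, ConceptRow] = field(default_factory=dict)
    descriptions: list[DescriptionRow] = field(default_factory=list)
    relationships: list[RelationshipRow] = field(default_factory=list)

    def add_concept(self, row: ConceptRow) -> None:
        if row.id in self.concepts:
            raise Rf2Error(f"duplicate concept id {row.id}")
        self.concepts[row.id] = row

    def validate(self) -> None:
        """Check referential integrity; raise Rf2Error listing the problems."""
        problems: list[str] = []
        for d in self.descriptions:
            if d.conceptId not in self.concepts:
                problems.append(f"description {d.id} references missing concept {d.conceptId}")
        for r in self.relationships:
            if r.sourceId not in self.concepts:
                problems.append(f"relationship {r.id} references missing source {r.sourceId}")
            if r.destinationId not in self.concepts:
                problems.append(f"relationship {r.id} references missing destination {r.destinationId}")
            if r.typeId not in self.concepts:
                problems.append(f"relationship {r.id} references missing type {r.typeId}")
        if problems:
            raise Rf2Error("snapshot failed validation:\n  " + "\n  ".join(problems))

    def fsn(self, concept_id: str) -> str | None:
        """Fully specified name of a concept, if an active FSN row exists."""
        for d in self.descriptions:
            if d.conceptId == concept_id and d.typeId == FSN_TYPE and d.active:
                return d.term
        return None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Rf2Snapshot):
            return NotImplemented
        return (
            self.concepts == other.concepts
            and sorted(self.descriptions, key=lambda d: d.id)
            == sorted(other.descriptions, key=lambda d: d.id)
            and sorted(self.relationships, key=lambda r: r.id)
            == sorted(other.relationships, key=lambda r: r.id)
        )


def _parse_bool(token: str, line: int) -> bool:
    if token == "1":
        return True
    if token == "0":
        return False
    raise Rf2Error(f"active flag must be 0 or 1, got {token!r} (line {line})")


def _read_table(path: str | Path, columns: tuple[str, ...]) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        lines = fh.read().split("\n")
    if not lines or lines[0].split("\t") != list(columns):
        raise Rf2Error(
            f"{path}: header must be {chr(9).join(columns)!r}, got {lines[0]!r}"
        )
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        fields = line.split("\t")
        if len(fields) != len(columns):
            raise Rf2Error(
                f"{path} line {lineno}: expected {len(columns)} columns, got {len(fields)}"
            )
        yield lineno, fields


def read_snapshot(
    concept_path: str | Path,
    description_path: str | Path,
    relationship_path: str | Path,
    validate: bool = True,
) -> Rf2Snapshot:
    """Parse the three snapshot tables.  Inactive rows are retained (the
    ``active`` flag is preserved for backward compatibility)."""
    snap = Rf2Snapshot()
    for lineno, f in _read_table(concept_path, CONCEPT_COLUMNS):
        try:
            snap.add_concept(ConceptRow(f[0], f[1], _parse_bool(f[2], lineno), f[3], f[4]))
        except Rf2Error as exc:
            raise Rf2Error(f"{concept_path} line {lineno}: {exc}") from None
    for lineno, f in _read_table(description_path, DESCRIPTION_COLUMNS):
        snap.descriptions.append(
            DescriptionRow(f[0], f[1], _parse_bool(f[2], lineno), f[3], f[4], f[5], f[6], f[7], f[8])
        )
    for lineno, f in _read_table(relationship_path, RELATIONSHIP_COLUMNS):
        try:
            group = int(f[6])
        except ValueError:
            raise Rf2Error(
                f"{relationship_path} line {lineno}: relationshipGroup must be an integer, got {f[6]!r}"
            ) from None
        try:
            snap.relationships.append(
                RelationshipRow(f[0], f[1], _parse_bool(f[2], lineno), f[3], f[4], f[5],
                                group, f[7], f[8], f[9])
            )
        except Rf2Error as exc:
            raise Rf2Error(f"{relationship_path} line {lineno}: {exc}") from None
    if validate:
        snap.validate()
    return snap


def read_snapshot_dir(directory: str | Path, validate: bool = True) -> Rf2Snapshot:
    d = Path(directory)
    return read_snapshot(d / CONCEPT_FILE, d / DESCRIPTION_FILE, d / RELATIONSHIP_FILE,
                         validate=validate)


def _fmt_bool(v: bool) -> str:
    return "1" if v else "0"


def write_snapshot(snapshot: Rf2Snapshot, directory: str | Path) -> tuple[Path, Path, Path]:
    """Write the three tables as tab-separated UTF-8 with sorted row order.

    Output is a pure function of the snapshot: two writes give identical bytes.
    """
    snapshot.validate()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = (d / CONCEPT_FILE, d / DESCRIPTION_FILE, d / RELATIONSHIP_FILE)

    def dump(path: Path, columns: tuple[str, ...], rows: Iterable[Iterable[str]]) -> None:
        body = "\n".join("\t".join(r) for r in rows)
        text = "\t".join(columns) + ("\n" + body if body else "") + "\n"
        path.write_text(text, encoding="utf-8", newline="")

    dump(paths[0], CONCEPT_COLUMNS,
         ([c.id, c.effectiveTime, _fmt_bool(c.active), c.moduleId, c.definitionStatusId]
          for c in sorted(snapshot.concepts.values(), key=lambda c: c.id)))
    dump(paths[1], DESCRIPTION_COLUMNS,
         ([x.id, x.effectiveTime, _fmt_bool(x.active), x.moduleId, x.conceptId,
           x.languageCode, x.typeId, x.term, x.caseSignificanceId]
          for x in sorted(snapshot.descriptions, key=lambda x: x.id)))
    dump(paths[2], RELATIONSHIP_COLUMNS,
         ([r.id, r.effectiveTime, _fmt_bool(r.active), r.moduleId, r.sourceId,
           r.destinationId, str(r.relationshipGroup), r.typeId,
           r.characteristicTypeId, r.modifierId]
          for r in sorted(snapshot.relationships, key=lambda r: r.id)))
    return paths


class TaxonomyIndex:
    """Reflexive-transitive closure over the active IS_A rows.

    Inactive rows never contribute edges (``include_inactive=True`` opts back
    in).  The IS_A graph must be acyclic; a cycle raises naming one witness.
    """

    def __init__(self, snapshot: Rf2Snapshot, include_inactive: bool = False) -> None:
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(snapshot.concepts)
        for r in snapshot.relationships:
            if r.typeId != IS_A:
                continue
            if not r.active and not include_inactive:
                continue
            self._graph.add_edge(r.sourceId, r.destinationId)  # child -> parent
        try:
            cycle = nx.find_cycle(self._graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise Rf2Error(f"IS_A graph contains a cycle: {path}")
        self._ancestors: dict[str, frozenset[str]] = {}
        self._descendants: dict[str, frozenset[str]] = {}

    @property
    def parent_map(self) -> Mapping[str, set[str]]:
        return {c: set(self._graph.successors(c)) for c in self._graph}

    def parents(self, concept_id: str) -> set[str]:
        if concept_id not in self._graph:
            return set()
        return set(self._graph.successors(concept_id))

    def children(self, concept_id: str) -> set[str]:
        if concept_id not in self._graph:
            return set()
        return set(self._graph.predecessors(concept_id))

    def ancestors(self, concept_id: str) -> frozenset[str]:
        """All strict ancestors (transitive parents)."""
        if concept_id not in self._graph:
            return frozenset()
        cached = self._ancestors.get(concept_id)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, concept_id))
            self._ancestors[concept_id] = cached
        return cached

    def descendants(self, concept_id: str) -> frozenset[str]:
        if concept_id not in self._graph:
            return frozenset()
        cached = self._descendants.get(concept_id)
        if cached is None:
            cached = frozenset(nx.ancestors(self._graph, concept_id))
            self._descendants[concept_id] = cached
        return cached

    def is_a_or_self(self, child: str, parent: str) -> bool:
        return child == parent or parent in self.ancestors(child)


def taxonomy_index(snapshot: Rf2Snapshot, include_inactive: bool = False) -> TaxonomyIndex:
    snapshot.validate()
    return TaxonomyIndex(snapshot, include_inactive=include_inactive)
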