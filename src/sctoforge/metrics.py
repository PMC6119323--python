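"""Ontology structure metrics and RF2 relationship-group statistics.

The metric formulas, since the usual metric tables never define them:

* the class graph is the named-subclass graph (subject, direct named
  superclass) of the ontology;
* *parents* / *children* are direct neighbours in that graph;
* *siblings* of a class are the other direct subclasses of any of its
  parents; averages are taken over classes that have the respective feature
  (classes with at least one sibling, at least one child, ...), excluding
  the roots;
* *depth* is counted in edges from a root (a class with no named parent);
* *axioms* counts logical class axioms; *annotations* counts annotation
  assertions (label + textual definition), not annotation properties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields

from .rf2 import IS_A, Rf2Snapshot
from .scto import Ontology

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricReport:
    classes: int
    axioms: int
    axioms_with_annotations: int
    object_properties: int
    data_properties: int
    max_parents: int
    avg_siblings: float
    max_children: int
    avg_children: float
    classes_gt25_children: int
    single_child_classes: int
    max_siblings: int
    subclass_axioms: int
    annotations: int
    max_depth: int

    def as_text(self) -> str:
        width = max(len(f.name) for f in fields(self))
        return "\n".join(f"{f.name:<{width}}  {getattr(self, f.name)}"
                         for f in fields(self))

    def as_dict(self) -> dict[str, float | int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def ontology_metrics(ont: Ontology) -> MetricReport:
    parents: dict[str, set[str]] = {c: set() for c in ont.classes}
    children: dict[str, set[str]] = {c: set() for c in ont.classes}
    for sub, sup in ont.subclass_edges():
        if sub in parents and sup in children:
            parents[sub].add(sup)
            children[sup].add(sub)

    roots = [c for c, ps in parents.items() if not ps]
    depth: dict[str, int] = {r: 0 for r in roots}
    frontier = list(roots)
    while frontier:  # longest path from a root, graph is acyclic
        nxt: list[str] = []
        for c in frontier:
            for child in children[c]:
                d = depth[c] + 1
                if depth.get(child, -1) < d:
                    depth[child] = d
                    nxt.append(child)
        frontier = nxt

    sibling_counts: list[int] = []
    for c in ont.classes:
        if not parents[c]:
            continue
        sibs = set()
        for p in parents[c]:
            sibs |= children[p]
        sibs.discard(c)
        sibling_counts.append(len(sibs))
    child_counts = [len(children[c]) for c in ont.classes if children[c]]

    n_annotations = ont.annotation_count()
    n_axioms = len(ont.class_axioms)
    positive_siblings = [s for s in sibling_counts if s > 0]
    return MetricReport(
        classes=len(ont.classes),
        axioms=n_axioms,
        axioms_with_annotations=n_axioms + n_annotations,
        object_properties=len(ont.object_properties),
        data_properties=len(ont.data_properties),
        max_parents=max((len(p) for p in parents.values()), default=0),
        avg_siblings=round(sum(positive_siblings) / len(positive_siblings), 2)
        if positive_siblings else 0.0,
        max_children=max((len(c) for c in children.values()), default=0),
        avg_children=round(sum(child_counts) / len(child_counts), 2)
        if child_counts else 0.0,
        classes_gt25_children=sum(1 for c in children.values() if len(c) > 25),
        single_child_classes=sum(1 for c in children.values() if len(c) == 1),
        max_siblings=max(sibling_counts, default=0),
        subclass_axioms=len(ont.subclass_edges()),
        annotations=n_annotations,
        max_depth=max(depth.values(), default=0),
    )


@dataclass(frozen=True)
class GroupStats:
    """Share of grouped non-IS_A rows and per-attribute shares of them."""

    total_non_isa: int
    grouped: int
    grouped_fraction: float  # percentage
    attribute_shares: dict[str, float]  # typeId -> % of grouped rows

    def as_text(self) -> str:
        lines = [
            f"non-IS_A relationships  {self.total_non_isa}",
            f"grouped (group != 0)    {self.grouped}",
            f"grouped_fraction        {self.grouped_fraction:.2f}%",
        ]
        for attr, share in sorted(self.attribute_shares.items(),
                                  key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"  {attr}  {share:.2f}%")
        return "\n".join(lines)


def rf2_group_stats(snapshot: Rf2Snapshot) -> GroupStats:
    """Fractions over the active non-IS_A rows of a snapshot."""
    snapshot.validate()
    rows = [r for r in snapshot.relationships if r.active and r.typeId != IS_A]
    grouped = [r for r in rows if r.relationshipGroup != 0]
    if not rows:
        warnings.warn("snapshot has no active non-IS_A relationships; "
                      "grouped_fraction defined as 0", stacklevel=2)
        return GroupStats(0, 0, 0.0, {})
    shares: dict[str, float] = {}
    if grouped:
        by_attr: dict[str, int] = {}
        for r in grouped:
            by_attr[r.typeId] = by_attr.get(r.typeId, 0) + 1
        shares = {a: 100.0 * n / len(grouped) for a, n in sorted(by_attr.items())}
    return GroupStats(
        total_non_isa=len(rows),
        grouped=len(grouped),
        grouped_fraction=100.0 * len(grouped) / len(rows),
        attribute_shares=shares,
    )
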