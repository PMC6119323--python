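# Methods

This note records the models, conventions, and design decisions behind
`sctoforge`, in the order the pipeline applies them.

## Expression language and dialects

The compositional-grammar parser accepts two dialects.  `standard` is the
conventional form: an optional definition-status prefix (`===` equivalent,
`<<<` subtype; `===` is the default and may be omitted), focus concepts
joined by `,` or `+`, a `:` introducing the refinement, `attr = value`
pairs, attribute groups in braces, nested expressions in parentheses after
`=`, numeric concrete values marked `#`, string values quoted.  `paper`
reproduces the looser style of older worked examples and differs in four
ways, each resolving a concrete ambiguity:

* a subject may precede the status symbol (`111613008 |...| === ...`); the
  split happens at the first status symbol outside parentheses, braces,
  and `|...|` terms.  The subject is retained on the AST for display but
  carries no semantics and never reaches the DL translation;
* juxtaposition of two concept references inside a refinement context is
  read as `name = value` (the diabetes example writes
  `363698007 |finding site| 113331007`);
* a parenthesized attribute set standing where a focus concept or
  attribute is expected is an attribute group (the skull-fracture example
  writes its two groups with plain parentheses after commas); parentheses
  immediately after `=` are always nested expressions.  Braces are groups
  in both dialects, which is why the two dialects agree on any text that
  uses braces-style groups only;
* the `:` before a refinement is optional.

Terms (`|...|` labels) are display-only: concept references compare equal
on the identifier alone, so stripping every term from an expression cannot
change what it parses to.  Identifiers stay strings end to end — SCTIDs
exceed the range where floats are exact, and the canonical order is the
lexicographic order of the digit strings.

## Canonical form

Canonicalization flattens conjunctions, removes duplicates, unwraps
singleton conjunctions, and sorts members by a total key: concept names
sort by their identifier string (which is what renders the needle-biopsy
combination as `129249002, 7246002`), and structured members sort by a
prefixed rendering so that names precede value restrictions, existentials,
role groups, and conjunctions deterministically.  The function is
idempotent and insensitive to member order; equivalence of an expression
with its canonical form is additionally asserted through the reasoner in
the test suite.

## Role groups

A group `{∃R.C ⊓ ∃S.D}` desugars to `∃RG.(∃R.C ⊓ ∃S.D) ⊓ ∃R.C ⊓ ∃S.D`:
one existential over the reserved role `RG`, *plus* the members hoisted as
direct conjuncts.  The hoisting is deliberate.  In the release data a
grouped relationship row still asserts its attribute of the source concept
— the group number only records which rows must be interpreted together —
and hoisting is exactly what turns the three redundancy-prevention
identities (below) into genuine logical equivalences rather than mere
normal-form conventions.  Under the pure `∃RG`-only reading, dropping an
ungrouped `∃R.C` that repeats inside a group would strictly weaken the
expression.  With hoisting, the classifier and the finite-model oracle
agree that every rewrite preserves equivalence.

Group-to-group subsumption falls out of the desugaring: a group entails
another precisely when its member conjunction entails the other's, so no
bespoke group matcher exists.

## Classification

The classifier is the standard EL completion-rule saturation for general
concept inclusions.  The TBox is structurally normalized: fresh names are
introduced (with defining equivalences) for complex subexpressions, role
groups are desugared first, and each concrete-value restriction maps to an
opaque atom keyed by (attribute, value) — two restrictions interact only
on exact value equality, since the fragment has no concrete-domain
semantics.  Saturation maintains subsumer sets `S(X)` and role edges under
the usual rules; role inclusions are closed reflexively-transitively;
domain restrictions are internalized as `∃R.⊤ ⊑ C`; range restrictions
apply at existential introduction (the edge target is a fresh name below
the filler and every applicable range class); disjointness contributes
`A ⊓ B ⊑ ⊥`, and ⊥ propagates backwards along role edges.  A name whose
subsumer set contains ⊥ is reported as unsatisfiable through a logged
warning and subsumes every name.

Expression-level subsumption internalizes the query: fresh names are
defined equivalent to both expressions and the extended TBox is
classified.  `naive_closure` recomputes the same relation by exhaustive
unindexed rule application — every rule against every atom on every pass —
and serves as the independent oracle for the worklist classifier.

### Qualifier policy

Whether a qualified expression is subsumed by its focus concept depends on
the qualifier: an episodicity refinement of a fever still is a fever, but
a finding asserted in a negating context ("known absent") is not an
instance of the finding.  The reasoner models this as configuration: a set
of context-attribute identifiers whose presence at the top level of the
subsumee suppresses subsumption by its focus concepts and their ancestors.
The default set contains only the finding-context attribute (408729009) as
a documented placeholder, because the context-carrying situation hierarchy
itself is out of scope.

## Counter-model search

`find_countermodel(tbox, a, b, max_domain)` looks for a finite model of
the TBox with an individual in `a` but not `b`.  Exhaustive search over
interpretations is infeasible even at six individuals, so the search is
constructive: build the canonical model of the saturated (internalized)
TBox restricted to the part reachable from the query individual, minimize
it — first by bisimulation quotient over the visible signature (extensions
of the supported constructors are bisimulation-invariant), then, if still
above the bound, by greedily merging individuals while the candidate
remains a verified counter-model — and finally probe seeded random
interpretations.  Every returned model is verified against the Table-style
set semantics (`is_model` plus an explicit extension witness); the search
never trusts the classifier's verdict.  The canonical construction makes
the search complete for the supported fragment whenever a counter-model
fits within the bound; `max_domain` is capped at 8 as a documented cost
bound, and the cross-validation in the test suite runs at 6.

## Redundancy elimination

Three rewrites run to a fixpoint, innermost level first, in the order
(3) within-group pruning, (2) group-vs-group pruning, (1) ungrouped
duplicates, with canonicalization between passes:

1. an ungrouped exists-restriction that repeats (structurally, after
   canonicalization) inside some group is dropped;
2. a group whose member conjunction is entailed by another group's is
   dropped (covers "same group with a more general filler");
3. within a group, an exists-restriction whose filler is strictly more
   general than a sibling's on the same role is dropped.

Filler comparisons use the cached name-name classification when both
fillers are names and full expression subsumption otherwise.  Ties
(mutually subsuming but distinct conjuncts) are broken by the canonical
ordering key, keeping the smaller; this makes the fixpoint unique.  The
rules are applied recursively inside nested fillers, which extends the
identities beyond the top level; equivalence preservation for that
extension is asserted by the reasoner over seeded random expressions
rather than assumed.

## Mapping table and scaffold

The shipped mapping covers the 19 top-level hierarchies: three are
excluded as having no ontological relevance (social context, situation
with explicit context, special concept), the linkage concept sits under
the `SNOMED CT Concept` root only, and the remaining 15 map into an
upper-level tree of OGMS/BFO stub labels (subsumption for 13, equivalence
for organism and specimen).  Together with the root mapping
`SNOMED CT Concept ⊑ entity`, the table holds 17 mappings — 14 subsumption
(82.35%), 2 equivalence (11.76%), 1 with no equivalent (5.88%) — and 16
modeled hierarchies.  This is the only assignment consistent with all the
published counts at once: 14 + 2 + 1 mappings cannot be drawn from 19
concepts of which 3 are excluded unless the root mapping is one of the
subsumptions.  The exact stub targets per hierarchy are configuration
(YAML) with documented defaults; the stub tree carries labels only — the
real OGMS/BFO artifacts are not imported.

The reified schema fixes 8 object properties (description and
source/destination/type links with their inverses, plus the symmetric
`Grouped_Relations`) and exactly 20 data properties, partitioned by the
RF2 columns they preserve: 5 for Concept, 8 for Description, 7 for
Relationship (source, destination, and type are object properties, and a
description's concept travels through the description link).  One
disjointness axiom spans the 15 hierarchy classes of the published list
(body structure is absent from that list and is left out).  Every class
and property carries a label and a textual-definition annotation.

Reification maps active IS_A rows to subclass axioms — never to an
object-property assertion — and every other row to a Relationship
individual holding its metadata; descriptions become Description
individuals.  A fully defined concept (definitionStatusId
900000000000073002) additionally receives an equivalence over its parents
and reified group restrictions; primitive concepts get subsumptions only.
The grouping rule is materialized directly: relationship individuals
sharing a source and an equal non-zero group number are linked pairwise
and symmetrically (the rule as published omits the same-source condition,
but a group number only identifies a group within one concept's rows, so
grouping across sources would be spurious).  Group 0 never links.

An alternate N-ary pattern (`reify_nary`, `forge build --nary`) models each
attribute row as a class instead: a subclass of its relationship-type
concept with a `has_location` link to the destination and universal
restrictions pinning the metadata fields to single literals, the source
concept being restricted through a per-attribute `has_<type>` property.
It preserves the relationship hierarchy's shape but inherits the known
limitations of N-ary modelling, so the individual-based schema is the
default.

Expression-to-axiom conversion emits either the plain pattern (conjunction
of classes and `IsSourceOf some (destination and type)` restrictions) or
the reified pattern, where each group's first restriction is linked to its
siblings by `Grouped_Relations exactly 1`.  Concrete values become a
lazily declared `Relationship_concreteValue` data-property restriction —
an extension beyond the 20-property scaffold, declared only when used.

## Emission profiles

Functional syntax is the canonical format: declarations, annotations, and
axioms are fully sorted, making emission a byte-deterministic pure
function suitable for golden-file comparison.  Manchester syntax is
display-only and mirrors the `Class:` / `SubClassOf:` / `EquivalentTo:`
block style of the published listings.  Because those listings use
qualified cardinality and universal restrictions that exceed the EL
fragment, two profiles exist: `dl` emits them as printed; `el_safe`
replaces `exactly 1 Grouped_Relations` by a plain existential and drops
`only` restrictions with a logged warning.

## SCM validation

Concept-model rules are (domain hierarchy, attribute, permitted value
hierarchies, groupable) tuples.  An attribute application — from an
expression (recursively, nested expressions contributing their focus
concepts as values and being validated themselves) or from a snapshot's
non-IS_A rows — is checked only when at least one rule mentions the
attribute: first that some rule's domain hierarchy covers the source
(descendant-or-self), then that a covering rule permits the value
(descendant-or-self of a permitted hierarchy, mirroring the convention
that descendants of a permitted value are permitted).  Violations are
data, not errors.  The default table carries the clinical-finding branches
the examples exercise (finding site, associated morphology, episodicity,
causative agent).

## Fixture generator

`paper_fixture()` is the deterministic study snapshot: all 46 concepts the
worked examples cite, their FSN descriptions, the IS_A placements the
examples state or imply, the heart-disease finding-site row with its
published field values, the skull-fracture rows in two groups, and the
tetralogy-of-Fallot rows in four morphology/site groups (with an ungrouped
variant for comparison).  Placements and rows the examples do not state —
where the tetralogy sites and morphologies attach, for instance — use real
identifiers but are fixture inventions, marked `synthetic=true` in a
sidecar manifest so tests can separate stated from invented structure.
The one fully defined concept is the skull fracture, whose rows mirror its
printed definition.

`random_taxonomy(config)` grows an acyclic IS_A DAG under a single
synthetic root (each concept drawing 1..`max_parents` parents among
earlier concepts), attaches `rows_per_concept` (default 2) attribute rows
per non-root concept over `n_attribute_types` synthetic attributes, and
gives each row a non-zero group with probability `grouped_fraction`,
pairing consecutive grouped rows so groups have at least two members.
Everything derives from one seeded generator, so equal configurations give
byte-identical snapshots.  The random structures emulate scale and shape,
not content: they contain no meaningful clinical semantics, no
descriptions beyond placeholders, and no concrete values, so tests passing
on them demonstrate algorithmic correctness (closures, classification,
counting), not terminological fidelity.

Random TBoxes for oracle testing (`random_tbox`) mix told subsumptions,
existentials on both sides, binary conjunctions, role inclusions, and
domain/range restrictions over digit-string names; random expressions mix
focus names, existentials, and role groups with shallow fillers — the
shapes the grammar produces.

## Problem sizes and tolerances

The oracle-equivalence checks classify 100 seeded TBoxes of 25 names and
4 roles and cross-validate 200 seeded expression pairs against
counter-model search at domain 6; redundancy rewrites are checked on 200
seeded grouped expressions; semantic soundness evaluates every derived
fixture subsumption in 50 constructed-and-verified random models; the
grouped-fraction recovery runs at ≥1000 rows with a 5-percentage-point
band.  The whole suite completes in a few seconds on one CPU.

## Limitations

* No ABox instance checking, incremental reclassification, nominals,
  concrete-domain reasoning, or general role chains.
* RF2 Full/Delta histories, reference sets, and module dependency
  resolution are out of scope; `effectiveTime` is stored verbatim.
* Inactive rows are parsed and preserved but excluded from the taxonomy
  index and the TBox unless explicitly included via a flag; whether
  inactive IS_A rows should influence classification is left to the
  caller.
* The Expression Constraint Language (ECL) and definition-status markers
  beyond `===`/`<<<` are not supported.
* The upper-level stub tree is a label scaffold, not the OGMS/BFO
  artifacts; equivalences and subsumptions into it are configuration, not
  derived alignments.
* Counter-model search is complete only for the supported fragment and
  within the domain bound; outside it the probe is best-effort.
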