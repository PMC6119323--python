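# sctoforge

Turn SNOMED CT terminology content into a formally consistent OWL 2
ontology.  SNOMED CT ships as tab-separated RF2 release tables (concepts,
descriptions, relationships) with no computable semantics: IS_A rows,
attribute rows, relationship groups, and post-coordinated expressions all
live outside any logic a reasoner can check.  `sctoforge` gives that content
a description-logic reading and an ontology artifact:

* **RF2 I/O** — read, validate, and write snapshot tables; index the IS_A
  taxonomy with memoized ancestor/descendant closures.
* **Compositional grammar** — parse post-coordinated expressions
  (combinations, refinements, attribute groups, nested refinements,
  concrete values, qualifications) into an AST, in both the standard
  dialect and an older worked-example dialect.
* **EL++ reasoning** — translate expressions into the lightweight
  description logic fragment (⊤, ⊥, concept names, ⊓, ∃R.C, GCIs, role
  inclusions, domain/range, disjointness) extended with a role-group
  construct `{...}`, and decide subsumption/equivalence by completion-rule
  saturation in polynomial time.  Independent oracles — an unindexed
  fixpoint classifier and a finite counter-model search — cross-check every
  answer, and the three redundancy-elimination rewrites for grouped
  expressions run to a canonical fixpoint.
* **SCTO building** — emit an upper-level scaffold aligned with OGMS/BFO
  stub classes, a reified component schema (`SNOMED CT component` with
  Concept / Description / Relationship subclasses, 8 object properties,
  20 data properties), concept-model (SCM) constraint checking, and
  materialized `Grouped_Relations` links between reified relationship rows.
* **OWL 2 output** — deterministic functional syntax (`.ofn`) and
  Manchester syntax (`.omn`), in a DL profile (with `exactly 1`
  linkages as in the published listings) or an EL-safe profile.

No licensed SNOMED CT release is needed: a bundled fixture generator
produces a miniature snapshot containing every concept and relationship
used by the worked examples, plus seeded random taxonomies for testing.

## The model

An expression such as *capsule containing 500 mg of amoxicillin* is written
in compositional grammar with one focus concept, a refinement, and an
attribute group holding a nested expression with a concrete value:

```
27658006 |amoxicillin|:
  411116001 |has dose form| = 385049006 |capsule|,
  {127489000 |has active ingredient| = 372687004 |amoxicillin|,
   111115 |has basis of strength| = (111115 |amoxicillin only|:
      111115 |strength magnitude| = #500,
      111115 |strength unit| = 258684004 |mg|)}
```

Translation maps focus concepts and ungrouped refinements to a conjunction
of names and existentials, groups to the brace construct, nesting to
existential fillers, and the definition status to the axiom kind (`===` → ≡,
`<<<` → ⊑).  `forge to-dl` prints the result:

```
$ forge to-dl "27658006 |amoxicillin|: 411116001 |has dose form| = ..."
≡ 27658006 ⊓ ∃411116001.385049006 ⊓ {∃127489000.372687004 ⊓
  ∃111115.(111115 ⊓ ∃111115.#500 ⊓ ∃111115.258684004)}
```

A role group `{∃R.C ⊓ ∃S.D}` is treated as `∃RG.(∃R.C ⊓ ∃S.D)` over one
reserved role *and* keeps its members as direct conjuncts — a grouped
attribute row still relates the source concept to its value; the group adds
co-occurrence structure.  Subsumption is decided by saturating the
normalized TBox under the standard EL completion rules; semantics follow
the usual set interpretation I = (Δ, ·^I), which the package also evaluates
directly on finite models as an executable oracle.

## Worked example

```
$ forge fixtures paper --out fixture/
$ forge normal-form "Needle biopsy of kidney === 7246002 |Kidney biopsy|, 129249002 |Needle biopsy|"
129249002, 7246002
$ forge subsumes --tbox fixture/ \
    "periodic fever accompanied by chills === 274640006: 246456000 = 81591007" \
    "274640006"
true
$ forge metrics --rf2 fixture/ | tail -4
non-IS_A relationships  14
grouped (group != 0)    12
grouped_fraction        85.71%
...
```

The first command writes the self-contained worked-example snapshot.  The
normal form is the canonical, term-free rendering used to measure
expression equivalence (focus concepts sorted lexicographically).  The
subsumption query shows a qualification: refining *fever with chills* with
`episodicity = periodic` yields a subtype of the focus concept.  The
metrics command reports ontology structure counts and the share of
relationship rows that carry a non-zero relationship group (12 of the 14
attribute rows in the fixture: the tetralogy-of-Fallot and skull-fracture
group pairs).

Building the full artifact:

```
$ forge build --rf2 fixture/ --out scto.ofn           # OWL 2 functional syntax
$ forge emit --rf2 fixture/ --syntax omn --profile dl # Manchester, as listed
```

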