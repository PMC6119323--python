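"""The worked-example compositional-grammar expressions shipped with the tool.

These are the standard SNOMED CT worked examples for pre- and post-coordination
(combination, refinement, attribute groups, nested refinements, concrete
values, qualification), written in the older "paper" dialect the parser
supports.  They double as the source of the bundled miniature fixture
snapshot: every SCTID referenced here exists in
:func:`sctoforge.fixtures.paper_fixture`.
"""

from __future__ import annotations

# Diabetes mellitus: pre-coordinated definition (primitive, <<<), with a
# juxtaposed finding-site refinement.
DIABETES = (
    "73211009 |Diabetes mellitus| <<< "
    "126877002 |disorder of glucose metabolism|, "
    "362969004 |disorder of endocrine system|, "
    "363698007 |finding site| 113331007 |structure of endocrine system|"
)

# Needle biopsy of kidney: combination of two focus concepts.
NEEDLE_BIOPSY = "Needle biopsy of kidney === 7246002 |Kidney biopsy|, 129249002 |Needle biopsy|"

# The printed normal form of NEEDLE_BIOPSY (term-free, lexicographic order).
NEEDLE_BIOPSY_NORMAL_FORM = "129249002, 7246002"

# Radius fracture: the basic refinement form.
RADIUS_FRACTURE = (
    "=== 125605004 |Fracture of bone|: 363698007 |Finding site| = 181940002 |Radius|"
)

# Removal of an ovarian structure using a laser device.
OVARY_LASER = (
    "=== 71388002 |procedure|: "
    "405815000 |procedure device| = 122456005 |laser device|, "
    "260686004 |method| = 129304002 |excision - action|, "
    "405813007 |procedure site - direct| = 15497006 |ovarian structure|"
)

# Closed skull fracture with intracranial injury: two attribute groups,
# written with parenthesized groups in the paper dialect.
CLOSED_SKULL_FRACTURE = (
    "111613008 |closed skull fracture with intracranial injury| === "
    "451000119106 |closed injury of head|, 371162008 |closed fracture of skull|, "
    "(116676008 |associated morphology| = 450695007 |closed traumatic abnormality|, "
    "363698007 |finding site| = 128319008 |intracranial structure|), "
    "(116676008 |associated morphology| = 20946005 |fracture, closed|, "
    "363698007 |finding site| = 89546000 |bone structure of cranium|)"
)

# Capsule containing 500 mg of amoxicillin: nested refinement with a numeric
# concrete value (#500) and a unit concept.  111115 is the conventional
# placeholder identifier for the strength attributes.
AMOXICILLIN_CAPSULE = (
    "27658006 |amoxicillin|: "
    "411116001 |has dose form| = 385049006 |capsule|, "
    "{127489000 |has active ingredient| = 372687004 |amoxicillin|, "
    "111115 |has basis of strength| = (111115 |amoxicillin only|: "
    "111115 |strength magnitude| = #500, 111115 |strength unit| = 258684004 |mg|)}"
)

STRENGTH_MAGNITUDE = "111115"
STRENGTH_UNIT_MG = "258684004"

# Periodic fever accompanied by chills: qualification with an episodicity
# qualifier; subsumed by its focus concept fever with chills.
PERIODIC_FEVER = (
    "periodic fever accompanied by chills === 274640006 |fever with chills|: "
    "246456000 |episodicity| = 81591007 |periodic|"
)

# Bacterial infectious disease of the left upper lobe of the lung: nested
# expression as an attribute value.
BACTERIAL_PNEUMONIA = (
    "87628006 |bacterial infectious disease|: "
    "246075003 |causative agent| = 9861002 |streptococcus pneumonia|, "
    "363698007 |finding site| = (45653009 |structure of upper lobe of lung|, "
    "272741003 |laterality| = 7771000 |left|)"
)

ALL_EXAMPLES: dict[str, str] = {
    "diabetes": DIABETES,
    "needle_biopsy": NEEDLE_BIOPSY,
    "radius_fracture": RADIUS_FRACTURE,
    "ovary_laser": OVARY_LASER,
    "closed_skull_fracture": CLOSED_SKULL_FRACTURE,
    "amoxicillin_capsule": AMOXICILLIN_CAPSULE,
    "periodic_fever": PERIODIC_FEVER,
    "bacterial_pneumonia": BACTERIAL_PNEUMONIA,
}
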