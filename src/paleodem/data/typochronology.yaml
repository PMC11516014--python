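# Default typochronological date spans (years BCE, closed intervals).
#
# Anchors: battle axes belong to the Middle Neolithic B (2850-2350 BCE,
# phases after Huebner/Schultrich, with late types K/L running into the
# earliest Late Neolithic and producing the 2350-2250 BCE overlap with the
# daggers); flint daggers follow the Lomborg type sequence with LNI
# (2350-1950 BCE) covering types I-III and LNII (1950-1700 BCE) types IV-VI.
# Per-subtype spans are editable working assumptions, not canon: replace
# this file (or pass explicit spans per record) to use your own phasing.
types:
  - {category: battle_axe, type_code: phase1, span_start: 2850, span_end: 2600}
  - {category: battle_axe, type_code: phase2, span_start: 2600, span_end: 2450}
  - {category: battle_axe, type_code: phase3, span_start: 2450, span_end: 2350}
  - {category: battle_axe, type_code: KL, span_start: 2350, span_end: 2250}
  - {category: flint_dagger, type_code: I, span_start: 2350, span_end: 2200}
  - {category: flint_dagger, type_code: II, span_start: 2250, span_end: 2050}
  - {category: flint_dagger, type_code: III, span_start: 2100, span_end: 1950}
  - {category: flint_dagger, type_code: IV, span_start: 1950, span_end: 1850}
  - {category: flint_dagger, type_code: V, span_start: 1900, span_end: 1750}
  - {category: flint_dagger, type_code: VI, span_start: 1800, span_end: 1700}
  - {category: flint_dagger, type_code: LNI, span_start: 2350, span_end: 1950}
  - {category: flint_dagger, type_code: LNII, span_start: 1950, span_end: 1700}
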