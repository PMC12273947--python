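# Synthetic default garbage-code map.
#
# This is a package-constructed stand-in, NOT an empirically derived map:
# it covers the garbage-code groups most relevant to external-cause
# surveillance of adolescents (undetermined intent, ill-defined causes,
# unspecified accidental exposure) with plausible target groups.  Replace
# with a study-specific map for real analyses.
garbage_codes:
  - {code_start: Y10, code_end: Y34, gc_group: undetermined_intent}
  - {code_start: R00, code_end: R99, gc_group: ill_defined}
  - {code_start: X59, code_end: X59, gc_group: unspecified_accident}

groups:
  undetermined_intent:
    mode: empirical
    targets: [suicide, homicide, other_accident]
  ill_defined:
    mode: proportional
    targets: [natural]
  unspecified_accident:
    mode: proportional
    targets: [road_traffic, other_accident]

target_definitions:
  - {code_start: A00, code_end: Q99, target_group: natural}
  - {code_start: V01, code_end: V89, target_group: road_traffic}
  - {code_start: W00, code_end: X58, target_group: other_accident}
  - {code_start: X85, code_end: Y09, target_group: homicide}
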