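# Chemical-modification presets for the three Cond-siRNA construct
# generations. Per-position chemistries are ILLUSTRATIVE defaults encoding
# the qualitative pattern of each generation; edit freely — presets are
# data, not code.
#
# Rule grammar: each rule selects positions on one strand either by a named
# region (resolved on the construct geometry) or an explicit 1-based
# inclusive [start, end] range, then assigns sugar chemistry (ribo | 2OMe |
# LNA) and/or backbone chemistry (PO | PS) over the selected residues /
# internal linkages. Conjugates attach to the 5' or 3' terminus.
presets:
  firstG:
    description: >
      First-generation construct: LNA substitutions on the sensor toehold
      for trigger affinity, reduced phosphorothioate protection limited to
      the toehold linkages, and one additional LNA at the middle-toehold
      nick locus. Illustrative positions.
    rules:
      - {strand: sensor, region: toehold, sugar: LNA}
      - {strand: sensor, region: toehold, backbone: PS}
      - {strand: sensor, region: middle_toehold, sugar: LNA}
  secondG:
    description: >
      Second generation: firstG pattern plus 2'-O-methyl modifications of
      the guide strand (3' overhang and the two 5'-terminal residues) for
      stability and reduced off-target activity. Illustrative positions.
    rules:
      - {strand: sensor, region: toehold, sugar: LNA}
      - {strand: sensor, region: toehold, backbone: PS}
      - {strand: sensor, region: middle_toehold, sugar: LNA}
      - {strand: guide, region: overhang, sugar: 2OMe}
      - {strand: guide, positions: [1, 2], sugar: 2OMe}
  cholConj:
    description: >
      Cholesterol-conjugated generation: secondG chemistry plus a 3'
      cholesterol-triethylene-glycol conjugate on the sensor for
      carrier-free uptake.
    rules:
      - {strand: sensor, region: toehold, sugar: LNA}
      - {strand: sensor, region: toehold, backbone: PS}
      - {strand: sensor, region: middle_toehold, sugar: LNA}
      - {strand: guide, region: overhang, sugar: 2OMe}
      - {strand: guide, positions: [1, 2], sugar: 2OMe}
      - {strand: sensor, conjugate3: chol-TEG}
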