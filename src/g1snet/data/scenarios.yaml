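# In-silico experiments for the NSCLC G1/S checkpoint model.
# KO = clamp 0 (loss of function), E1 = clamp 1 (gain of function).
input_node: DNA_Damage
scenarios:
  ANRIL_E1:
    clamps:
      ANRIL: 1
    expected_phenotypes:
    - Proliferation
    input: 0
    note: sponge overexpression keeps miR-34a OFF
  ANRIL_KO:
    clamps:
      ANRIL: 0
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    note: miR-34a ON in every fixed point
  ANRIL_KO_UFC1_KO:
    clamps:
      ANRIL: 0
      UFC1: 0
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    note: 'double sponge knockdown: increased miR-34a expression'
  ANRIL_KO_miR34a_E1:
    clamps:
      ANRIL: 0
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    reported_probabilities:
      Apoptosis: 0.4
      Senescence: 0.6
  ANRIL_KO_miR34a_KO:
    clamps:
      ANRIL: 0
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
  Myc_E1:
    clamps:
      Myc: 1
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: miR-34a OFF, apoptosis only
  Myc_KO:
    clamps:
      Myc: 0
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    note: lncRNAs OFF in every fixed point
  UFC1_E1:
    clamps:
      UFC1: 1
    expected_phenotypes:
    - Proliferation
    input: 0
    note: sponge overexpression keeps miR-34a OFF
  UFC1_KO:
    clamps:
      UFC1: 0
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    note: miR-34a ON in every fixed point
  UFC1_KO_miR34a_E1:
    clamps:
      UFC1: 0
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    reported_probabilities:
      Apoptosis: 0.4
      Senescence: 0.6
  UFC1_KO_miR34a_KO:
    clamps:
      UFC1: 0
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
  WT_damage:
    clamps: {}
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    note: 'wild type under sustained DNA damage: bistable'
    reported_probabilities:
      Apoptosis: 0.8
      Senescence: 0.2
  WT_no_damage:
    clamps: {}
    expected_phenotypes:
    - Proliferation
    input: 0
    note: 'unstressed wild type: single proliferative fixed point'
  miR34a_E1:
    clamps:
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    note: lncRNAs OFF in every fixed point
  miR34a_E1_E2F1_E1_ANRIL_E1:
    clamps:
      ANRIL: 1
      E2F1: 1
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/E2F1/ANRIL'
  miR34a_E1_E2F1_E1_ANRIL_KO:
    clamps:
      ANRIL: 0
      E2F1: 1
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/E2F1/ANRIL'
  miR34a_E1_E2F1_E1_UFC1_E1:
    clamps:
      E2F1: 1
      UFC1: 1
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/E2F1/UFC1'
  miR34a_E1_E2F1_E1_UFC1_KO:
    clamps:
      E2F1: 1
      UFC1: 0
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/E2F1/UFC1'
  miR34a_E1_E2F1_KO_ANRIL_E1:
    clamps:
      ANRIL: 1
      E2F1: 0
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    note: 'circuit screen: miR34a/E2F1/ANRIL'
  miR34a_E1_E2F1_KO_ANRIL_KO:
    clamps:
      ANRIL: 0
      E2F1: 0
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    note: 'circuit screen: miR34a/E2F1/ANRIL'
  miR34a_E1_E2F1_KO_UFC1_E1:
    clamps:
      E2F1: 0
      UFC1: 1
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    note: 'circuit screen: miR34a/E2F1/UFC1'
  miR34a_E1_E2F1_KO_UFC1_KO:
    clamps:
      E2F1: 0
      UFC1: 0
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    note: 'circuit screen: miR34a/E2F1/UFC1'
  miR34a_E1_Myc_E1_ANRIL_E1:
    clamps:
      ANRIL: 1
      Myc: 1
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/Myc/ANRIL'
  miR34a_E1_Myc_E1_ANRIL_KO:
    clamps:
      ANRIL: 0
      Myc: 1
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/Myc/ANRIL'
  miR34a_E1_Myc_KO_ANRIL_E1:
    clamps:
      ANRIL: 1
      Myc: 0
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    note: 'circuit screen: miR34a/Myc/ANRIL'
  miR34a_E1_Myc_KO_ANRIL_KO:
    clamps:
      ANRIL: 0
      Myc: 0
      miR34a: 1
    expected_phenotypes:
    - Apoptosis
    - Senescence
    input: 1
    note: 'circuit screen: miR34a/Myc/ANRIL'
  miR34a_KO:
    clamps:
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: senescence abrogated, apoptosis only
  miR34a_KO_E2F1_E1_ANRIL_E1:
    clamps:
      ANRIL: 1
      E2F1: 1
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/E2F1/ANRIL'
  miR34a_KO_E2F1_E1_ANRIL_KO:
    clamps:
      ANRIL: 0
      E2F1: 1
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/E2F1/ANRIL'
  miR34a_KO_E2F1_E1_UFC1_E1:
    clamps:
      E2F1: 1
      UFC1: 1
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/E2F1/UFC1'
  miR34a_KO_E2F1_E1_UFC1_KO:
    clamps:
      E2F1: 1
      UFC1: 0
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/E2F1/UFC1'
  miR34a_KO_E2F1_KO_ANRIL_E1:
    clamps:
      ANRIL: 1
      E2F1: 0
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/E2F1/ANRIL'
  miR34a_KO_E2F1_KO_ANRIL_KO:
    clamps:
      ANRIL: 0
      E2F1: 0
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/E2F1/ANRIL'
  miR34a_KO_E2F1_KO_UFC1_E1:
    clamps:
      E2F1: 0
      UFC1: 1
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/E2F1/UFC1'
  miR34a_KO_E2F1_KO_UFC1_KO:
    clamps:
      E2F1: 0
      UFC1: 0
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/E2F1/UFC1'
  miR34a_KO_Myc_E1_ANRIL_E1:
    clamps:
      ANRIL: 1
      Myc: 1
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/Myc/ANRIL'
  miR34a_KO_Myc_E1_ANRIL_KO:
    clamps:
      ANRIL: 0
      Myc: 1
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/Myc/ANRIL'
  miR34a_KO_Myc_KO_ANRIL_E1:
    clamps:
      ANRIL: 1
      Myc: 0
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/Myc/ANRIL'
  miR34a_KO_Myc_KO_ANRIL_KO:
    clamps:
      ANRIL: 0
      Myc: 0
      miR34a: 0
    expected_phenotypes:
    - Apoptosis
    input: 1
    note: 'circuit screen: miR34a/Myc/ANRIL'
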