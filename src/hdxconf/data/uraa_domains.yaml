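# Reconstructed UraA domain definitions (E. coli uracil permease, 429 aa).
#
# The residue ranges below are approximate reconstructions from the
# published topology of the 14-TM 7TMIR fold: the deposited coordinate
# entries do not come with printed domain boundaries, so these defaults
# are a best-effort reading and are meant to be edited by the user when
# exact ranges are known.  Anchors that are well determined: the
# cytoplasmic spacer helix is flanked by Gly-112 and Pro-121, the external
# spacer helix by Gly-320 and Pro-330, the external hinge point lies
# between Cys-318 and Val-319, and the substrate binding site involves
# Glu-241, His-245, and Glu-290.
reconstructed: true
chain: A
transmembrane:
  TM1: [8, 36]
  TM2: [42, 65]
  TM3: [70, 92]
  TM4: [95, 111]
  TM5: [122, 145]
  TM6: [150, 175]
  TM7: [180, 205]
  TM8: [225, 250]
  TM9: [255, 278]
  TM10: [283, 305]
  TM11: [308, 318]
  TM12: [331, 355]
  TM13: [360, 385]
  TM14: [395, 420]
# core/gate split of the elevator architecture
domains:
  transport: [TM1, TM2, TM3, TM4, TM8, TM9, TM10, TM11]
  scaffold: [TM5, TM6, TM7, TM12, TM13, TM14]
linkers:
  cytoplasmic: [108, 125]   # TM4-5 linker containing the spacer helix
  external: [315, 335]      # TM11-12 linker containing the spacer helix
spacer_helices:
  cytoplasmic: [113, 120]
  external: [321, 329]
binding_site: [241, 245, 290]
hinge_point: [318, 319]
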