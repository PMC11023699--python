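# Conventional PANSS three-factor model: every item in exactly one subscale.
name: three_factor
full_coverage: true
subscales:
  Positive: [P1, P2, P3, P4, P5, P6, P7]
  Negative: [N1, N2, N3, N4, N5, N6, N7]
  General: [G1, G2, G3, G4, G5, G6, G7, G8, G9, G10, G11, G12, G13, G14, G15, G16]
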