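# Five-factor consensus model (20-item): Positive, Negative, Disorganized,
# Excited, Depressed; by design it does not cover all 30 items.
name: five_factor
full_coverage: false
subscales:
  Positive: [P1, P3, P5, G9]
  Negative: [N1, N2, N3, N4, N6, G7]
  Disorganized: [P2, N5, G11]
  Excited: [P4, P7, G8, G14]
  Depressed: [G2, G3, G6]
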