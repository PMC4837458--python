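# Default PPR code table.
#
# Dialect: `codes` maps a two-letter code (amino acids at repeat positions
# 5 and 35) either to a list of recognized bases (the profile then places
# `specificity_mass` on that set, split equally, remainder uniform on the
# other bases) or to an explicit {A,C,G,U} probability map. `fallbacks`
# maps a position-5 amino acid to an explicit profile used when no exact
# code entry exists.
specificity_mass: 0.90
codes:
  ND: [U]
  NS: [C]
  SN: [A]
  TD: [G]
  NN: [U, C]
  TN: [A]
  SD: [G]
fallbacks:
  # Asn at 5 -> pyrimidine preference
  N: {U: 0.35, C: 0.35, A: 0.15, G: 0.15}
  # Ser/Thr at 5 -> purine preference
  S: {A: 0.35, G: 0.35, U: 0.15, C: 0.15}
  T: {A: 0.35, G: 0.35, U: 0.15, C: 0.15}
  # small residues at 5 accommodate purines but with little specificity
  A: {A: 0.30, G: 0.30, U: 0.20, C: 0.20}
  G: {A: 0.30, G: 0.30, U: 0.20, C: 0.20}
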