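# Synthetic dPPR scaffold definition (constructed stand-in).
#
# The 35-aa repeat template is a constructed consensus-style helical-hairpin
# sequence, NOT the published designer-repeat sequence: it reproduces the
# architectural features that matter to this toolkit (exactly 35 residues,
# programmable code slots at positions 5 and 35, a hydrophobic clamp valine
# at position 2 and the phosphate-binding lysine at position 13) and is
# labelled synthetic accordingly. The NTD/CTD caps are likewise synthetic
# helical sequences standing in for the natural PPR10-derived terminal
# domains; their lengths (51 and 49 aa) are chosen so that the crystal
# construct numbering (construct residues 123-572, repeats 174-523 for a
# ten-repeat design) is reproduced by a numbering offset of 122.
template: LVTYNTLIDGLAKAGKLDEALELFEEMREKGIKPD
slot_positions: [5, 35]
special_positions:
  2: V   # hydrophobic clamp
  13: K  # phosphate-binding lysine
ntd: MGSVSNALEALVAERSRDLVRSGDLSGALEVFSEAVRSGVRLNAYSYNALI
ctd: VTYNSLMSGLGKAGRARDALALFDRMRASGVAPNVVSYNTLLDALARSG
crystal_numbering_offset: 122
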