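# HIV LTR-III quadruplex-duplex annotation.
#
# The 28-nt sequence folds into a three-tetrad G4 whose 12-nt diagonal
# loop (G3-T14) carries a GC duplex stem; the quadruplex-duplex junction
# is formed by A4 and T14.  Duplex pairs follow from Watson-Crick
# complementarity of the stem strands (G5:C13, G6:C12, C7:G11).
# Tetrad membership is intentionally left empty: fill it with
# detect_tetrads() on a deposited structure.
sequence: d[GGGAGGCGTGGCCTGGGCGGGACTGGGG]
tetrads: []
loops:
  - {class: propeller, range: [18, 18]}
  - {class: V-shaped, range: [25, 26]}
  - {class: lateral, range: [22, 24]}
  - {class: diagonal, range: [3, 14]}
duplex_pairs: [[5, 13], [6, 12], [7, 11]]
junction: [4, 14]
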