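# Topology annotation for human AQP2 (author numbering).
# Helix boundaries are APPROXIMATE: they are chosen to be consistent with
# the structural-location labels of the packaged variant catalog
# (table2.tsv) and with the half-helix/motif positions (NPA boxes at
# N68-P69-A70 and N184-P185-A186; ar/R selectivity filter around
# H172/C181/R187; regulatory C-tail phosphosites S256/S261).  They are not
# crystallographic DSSP assignments.
helix_ranges:
  H1: [12, 35]
  H2: [40, 64]
  HB: [67, 78]
  H3: [85, 108]
  H4: [126, 150]
  H5: [155, 180]
  HE: [185, 195]
  H6: [198, 218]
loops:
  loop A: [36, 39]
  loop B: [65, 66]
  loop C: [109, 125]
  loop D: [151, 154]
  loop E: [181, 184]
c_tail_start: 226
phosphosites: [256, 261]
npa_residues: [68, 69, 70, 184, 185, 186]
arR_residues: [172, 181, 187]
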