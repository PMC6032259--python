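# Experimental coordinates (user-supplied)

Analyses of the real human aquaporin structures need the corresponding PDB
entries, which are not redistributed with this package.  To enable them,
download the files and place them here as plain-text PDB:

    data/structures/4NEF.pdb   # human AQP2 tetramer, 2.75 Å
    data/structures/4OJ2.pdb   # human AQP2 monomer incl. C-tail to V257
    data/structures/3D9S.pdb   # human AQP5 tetramer, 2.00 Å
    data/structures/AQP8_model.pdb  # user-built AQP8 homology model

e.g. `curl -O https://files.rcsb.org/download/4NEF.pdb`.

Tests and analyses that depend on these coordinates fail with an explicit
message when the files are absent; everything else in the package runs on
synthetic structures and needs nothing from this directory.
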