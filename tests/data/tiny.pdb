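ATOM      1  N   ALA A  26       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A  26       0.000   0.000   0.000  1.00 20.00           C
ATOM      3  C   ALA A  26       0.000   0.000   0.000  1.00 30.00           C
ATOM      4  N   LEU A  27       0.000   0.000   0.000  1.00 12.00           N
ATOM      5  CA ALEU A  27       0.000   0.000   0.000  0.70 10.00           C
ATOM      6  CA BLEU A  27       0.000   0.000   0.000  0.30 50.00           C
ATOM      7  N   GLY A  28       0.000   0.000   0.000  1.00  5.00           N
ATOM      8  CA  GLY A  28       0.000   0.000   0.000  1.00 15.00           C
ATOM      9  H   GLY A  28       0.000   0.000   0.000  1.00 40.00           H
ATOM     10  CA  SER A  29       0.000   0.000   0.000  1.00  8.00           C
ATOM     11  CA  GLU A  30       0.000   0.000   0.000  1.00 30.00           C
ATOM     12  CA  LYS A  31       0.000   0.000   0.000  1.00 40.00           C
ATOM     13  CA  VAL B   1       0.000   0.000   0.000  1.00  7.00           C
HETATM   14  O   HOH A 101       0.000   0.000   0.000  1.00 99.00           O
END
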