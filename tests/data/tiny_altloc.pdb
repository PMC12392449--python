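HEADER    TEST FIXTURE
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA AALA A   1       2.500   2.000   3.000  0.40  0.00           C
ATOM      3  CA BALA A   1       2.600   2.100   3.000  0.60  0.00           C
ATOM      4  C   ALA A   1       3.500   3.000   4.000  1.00  0.00           C
ATOM      5  H   ALA A   1       0.500   1.500   2.500  1.00  0.00           H
ATOM      6 HB1  ALA A   1       0.400   1.400   2.400  1.00  0.00           H
HETATM    7  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O
HETATM    8 CL   CL  A 102       8.000   8.000   8.000  1.00  0.00          CL
END
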