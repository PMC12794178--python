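# atom_name charge_e (fixture, symmetrized)
RH     -0.300000
C1      0.008000
C2      0.008000
C3      0.008000
C4      0.008000
C5      0.008000
C6     -0.140000
C7     -0.140000
C8     -0.140000
C9     -0.140000
C10    -0.140000
H1      0.100000
H2      0.100000
H3      0.100000
H4      0.100000
H5      0.100000
H6      0.100000
H7      0.100000
H8      0.100000
H9      0.100000
H10     0.100000
H11     0.100000
H12     0.100000
H13     0.100000
H14     0.100000
H15     0.100000
N1     -0.354000
C11     0.296000
C12    -0.054000
C13    -0.054000
C14    -0.054000
C15    -0.054000
H16     0.191000
H17     0.191000
H18     0.131000
H19     0.191000
N2     -0.354000
C16     0.296000
C17    -0.054000
C18    -0.054000
C19    -0.054000
C20    -0.054000
H20     0.191000
H21     0.191000
H22     0.131000
H23     0.191000
CL     -0.400000
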