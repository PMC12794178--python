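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
N1     -0.349091
C11     0.300909
C12    -0.049091
C13    -0.049091
C14    -0.049091
C15    -0.049091
H16     0.195909
H17     0.195909
H18     0.135909
N2     -0.349091
C16     0.300909
C17    -0.049091
C18    -0.049091
C19    -0.049091
C20    -0.049091
H19     0.195909
H20     0.195909
H21     0.135909
C21    -0.049091
C22    -0.049091
H22     0.195909
H23     0.195909
CL     -0.400000
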