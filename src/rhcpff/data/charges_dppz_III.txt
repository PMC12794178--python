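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
N1     -0.324063
C11     0.325937
C12    -0.024063
C13    -0.024063
C14    -0.024063
C15    -0.024063
H16     0.220938
H17     0.220938
H18     0.160938
N2     -0.324063
C16     0.325937
C17    -0.024063
C18    -0.024063
C19    -0.024063
C20    -0.024063
H19     0.220938
H20     0.220938
H21     0.160938
C21    -0.024063
C22    -0.024063
N3     -0.424063
C23    -0.024063
C24    -0.024063
N4     -0.424063
C25    -0.024063
H22     0.220938
C26    -0.024063
H23     0.220938
C27    -0.024063
H24     0.220938
C28    -0.024063
H25     0.220938
CL     -0.400000
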