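# atom_name charge_e (fixture, symmetrized)
RH     -0.700000
C1     -0.050000
C2     -0.050000
C3     -0.050000
C4     -0.050000
C5     -0.050000
C6     -0.120000
C7     -0.120000
C8     -0.120000
C9     -0.120000
C10    -0.120000
H1      0.080000
H2      0.080000
H3      0.080000
H4      0.080000
H5      0.080000
H6      0.080000
H7      0.080000
H8      0.080000
H9      0.080000
H10     0.080000
H11     0.080000
H12     0.080000
H13     0.080000
H14     0.080000
H15     0.080000
N1     -0.372273
C11     0.277727
C12    -0.072273
C13    -0.072273
C14    -0.072273
C15    -0.072273
H16     0.172727
H17     0.172727
H18     0.112727
N2     -0.372273
C16     0.277727
C17    -0.072273
C18    -0.072273
C19    -0.072273
C20    -0.072273
H19     0.172727
H20     0.172727
H21     0.112727
C21    -0.072273
C22    -0.072273
H22     0.172727
H23     0.172727
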