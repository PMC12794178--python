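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
N1     -0.379500
C11     0.270500
C12    -0.079500
C13    -0.079500
C14    -0.079500
C15    -0.079500
H16     0.165500
H17     0.165500
H18     0.105500
H19     0.165500
N2     -0.379500
C16     0.270500
C17    -0.079500
C18    -0.079500
C19    -0.079500
C20    -0.079500
H20     0.165500
H21     0.165500
H22     0.105500
H23     0.165500
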