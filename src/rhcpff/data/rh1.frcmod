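Custom sigma-bonded model parameters for the neutral Cp*Rh(I) alpha-diimine complex
MASS
M1    102.9055    0.0000
Y1     12.0100    0.3600
Y6     14.0100    0.5300
YC     12.0100    0.3600

BOND
M1-Y1     58.6000      2.1600
M1-Y6     89.8000      2.0600
Y1-Y1    354.2500      1.4500
Y6-YC    386.4900      1.3600
YC-YC    354.2500      1.4000

ANGLE
Y1-M1-Y6     30.0000    143.0000
Y6-M1-Y6    139.4900    108.0000
M1-Y6-ca    194.5900    125.1600
M1-Y6-YC    194.5900    126.0000
Y1-M1-Y1      0.0000     72.0000
M1-Y1-Y1      0.0000     90.0000
M1-Y1-c3      0.0000    125.0000

DIHE

NONBON
  M1      1.4645      0.0530
  Y1      1.9080      0.0860
  Y6      1.8240      0.1700
  YC      1.9080      0.0860
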