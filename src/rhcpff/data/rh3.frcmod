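Custom sigma-bonded model parameters for the cationic Cp*Rh(III) chloride alpha-diimine complex
MASS
M1    102.9055    0.0000
Y1     12.0100    0.3600
Y6     14.0100    0.5300
Y8     35.4500    1.9100
YC     12.0100    0.3600

BOND
M1-Y1     66.6000      2.0800
M1-Y6     70.2000      2.0900
Y1-Y1    354.2500      1.4700
Y6-YC    386.4900      1.3400
YC-YC    354.2500      1.4700
M1-Y8     81.4000      2.4100

ANGLE
Y1-M1-Y6     30.0000    129.0000
Y6-M1-Y6    154.0600     84.0000
M1-Y6-ca    139.3600    123.7100
M1-Y6-YC    139.3600    118.0000
Y1-M1-Y8     30.0000    125.0000
Y6-M1-Y8     30.0000    101.0000
Y1-M1-Y1      0.0000     72.0000
M1-Y1-Y1      0.0000     90.0000
M1-Y1-c3      0.0000    125.0000

DIHE

NONBON
  M1      1.4645      0.0530
  Y1      1.9080      0.0860
  Y6      1.8240      0.1700
  Y8      1.9480      0.2650
  YC      1.9080      0.0860
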