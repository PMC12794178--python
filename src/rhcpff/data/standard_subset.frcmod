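Minimal standard-type parameter subset (general-Amber-force-field style nominal values) closing every term of the Cp*Rh alpha-diimine family, plus a rigid 3-site water
MASS
ca     12.0100    0.3600
nb     14.0100    0.5300
cl     35.4500    1.9100
c3     12.0100    0.8780
ha      1.0080    0.1350
h4      1.0080    0.1350
hc      1.0080    0.1350
ow     16.0000    0.0000
hw      1.0080    0.0000

BOND
ca-ca    478.4000      1.3870
ca-ha    344.3000      1.0870
ca-h4    342.9000      1.0870
ca-nb    483.1000      1.3420
c3-ca    323.5000      1.5130
c3-hc    337.3000      1.0920
hw-ow    553.0000      0.9572
hw-hw    553.0000      1.5136

ANGLE
ca-ca-ca     67.2000    119.9700
ca-ca-ha     48.5000    120.0100
ca-ca-nb     68.8000    122.6300
ca-nb-ca     68.3000    117.2200
h4-ca-nb     51.5000    116.0300
ca-ca-h4     48.1000    120.3400
c3-ca-ca     63.8000    120.7700
ca-c3-hc     46.8000    110.4700
hc-c3-hc     39.4000    107.5800
hw-ow-hw    100.0000    104.5200

DIHE
X -ca-ca-X     4     14.5000    180.0000     2
X -ca-nb-X     2      9.6000    180.0000     2
X -c3-ca-X     6      0.0000      0.0000     2

NONBON
  ca      1.9080      0.0860
  nb      1.8240      0.1700
  cl      1.9480      0.2650
  c3      1.9080      0.1094
  ha      1.4590      0.0150
  h4      1.4090      0.0150
  hc      1.4870      0.0157
  ow      1.7683      0.1520
  hw      0.0000      0.0000
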