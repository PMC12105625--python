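compound,kind,pH,SMD_DFT,SMD_DFT_H2O,SMD_CBS,SMD_CBS_H2O,experiment
A,m1,7.0,1.54,1.51,1.83,1.79,1.32
T,m1,7.0,1.91,1.81,2.15,2.05,1.29
G,m1,7.0,1.25,1.19,1.48,1.45,1.04
C,m1,7.0,1.75,1.72,1.91,1.89,1.44
U,m1,7.0,2.25,2.11,2.44,2.32,1.34
1mG,m1,7.0,1.20,1.18,1.43,1.44,1.06
X,m2,7.0,1.58,1.48,1.75,1.66,0.93
hX,m2,7.0,1.82,1.74,2.04,1.98,1.16
hX,m2,9.0,1.37,1.35,1.54,1.52,1.05
1mInd,m1,7.0,0.91,0.97,1.19,1.21,1.23
Ind,m1,7.0,1.03,0.99,1.33,1.30,1.24
PhOH,m1,7.0,1.57,1.32,1.84,1.64,1.35
tAn,m1,7.0,1.28,1.34,1.56,1.58,1.45
Caf,m1,7.0,1.54,1.59,1.79,1.81,1.50
X,m1_raw,,1.83,1.69,2.00,1.89,
d_X,m1_raw,,0.81,0.78,0.94,0.92,
hX,m1_raw,,1.83,1.75,2.05,1.99,
d_hX,m1_raw,,1.00,1.04,1.14,1.14,
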