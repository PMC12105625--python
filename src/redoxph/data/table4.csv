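compound,M3_SMD_DFT,M4_SMD_DFT,M3_SMD_DFT_H2O,M4_SMD_DFT_H2O,M3_SMD_CBS,M4_SMD_CBS,M3_SMD_CBS_H2O,M4_SMD_CBS_H2O,experiment
A,1.20,1.62,1.25,1.62,1.40,1.82,1.44,1.83,1.32
T,1.19,1.53,1.23,1.50,1.37,1.79,1.39,1.75,1.29
G,0.94,1.35,0.95,1.31,1.13,1.55,1.15,1.51,1.04
C,1.43,2.02,1.46,1.98,1.57,2.19,1.60,2.17,1.44
U,1.42,1.71,1.45,1.69,1.57,1.96,1.57,1.91,1.34
1mG,0.90,1.34,0.94,1.35,1.11,1.55,1.13,1.55,1.06
X,1.00,1.18,0.95,1.11,1.16,1.38,1.11,1.31,0.93
hX,1.30,1.61,1.29,1.53,1.45,1.76,1.44,1.74,1.16
1mInd,,,,,,,,,1.23
Ind,0.94,1.84,0.93,1.65,0.97,1.89,0.99,1.78,1.24
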