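compound,AIE_DFT,AIE_CBS,AIE_exp,Eac_SMD_DFT,Eac_SMD_CBS,Eac_exp
A,8.01,8.29,8.26,1.42,1.70,1.72
T,8.68,8.92,8.87,1.66,1.90,1.87
G,7.62,7.81,7.77,1.03,1.26,1.25
C,8.44,8.69,8.68,1.54,1.69,1.90
U,9.16,9.35,8.68,2.01,2.21,>2.15
1mInd,7.25,7.52,7.40,,,
Ind,7.46,7.76,7.76,,,
PhOH,8.22,8.50,8.51,,,
tAn,7.65,7.93,7.93,,,
4mAnl,7.14,7.44,7.37,0.52,0.83,0.78
An,7.93,8.23,8.24,1.33,1.63,1.62
Napht,7.74,8.08,8.14,1.23,1.57,1.54
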