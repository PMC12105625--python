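compound,SMD_DFT,SMD_DFT_H2O,SMD_CBS,SMD_CBS_H2O,is_anchor
C,1.44,1.44,1.44,1.44,True
5mC,1.34,1.34,1.35,1.37,False
5hmC,1.36,1.34,1.41,1.42,False
5fC,1.41,1.43,1.43,1.46,False
5dhmC,1.40,1.41,1.47,1.45,False
5caC,1.23,1.21,1.27,1.37,False
d_5caC,0.88,0.84,0.84,1.04,False
1mC,1.78,1.75,1.81,1.77,False
1m5mC,1.70,1.74,1.70,1.75,False
1m5hmC,1.70,1.59,1.80,1.76,False
1m5fC,1.84,1.80,1.86,1.83,False
1m5dhmC,1.49,1.44,1.79,1.69,False
1m5caC,1.23,1.29,1.49,1.47,False
d_1m5caC,0.91,1.05,1.37,1.28,False
U,1.34,1.34,1.34,1.34,True
T,1.25,1.21,1.25,1.10,False
5hmU,1.29,1.24,1.31,1.26,False
5fU,1.32,1.40,1.31,1.33,False
5dhmU,1.29,1.54,1.33,1.57,False
5caU,1.36,1.39,1.33,1.37,False
d_5caU,0.78,0.88,0.59,0.69,False
1mU,1.62,1.60,1.64,1.65,False
1mT,1.37,1.46,1.51,1.51,False
1m5hmU,1.51,1.50,1.54,1.49,False
1m5fU,1.65,1.61,1.71,1.68,False
1m5dhmU,1.44,1.50,1.54,1.53,False
1m5caU,1.42,1.42,1.63,1.68,False
d_1m5caU,0.93,0.93,1.29,1.34,False
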