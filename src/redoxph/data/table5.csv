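compound,M1_SMD_DFT,M1_SMD_DFT_H2O,M1_SMD_CBS,M1_SMD_CBS_H2O,M4_SMD_DFT,M4_SMD_DFT_H2O,M4_SMD_CBS,M4_SMD_CBS_H2O,experiment
C,1.75,1.73,1.91,1.90,2.03,2.00,2.20,2.18,1.44
5mC,1.50,1.50,1.68,1.71,1.85,1.82,2.05,2.07,
5hmC,1.66,1.63,1.84,1.87,1.90,1.83,2.15,2.14,
5fC,2.15,2.11,2.22,2.24,1.98,1.97,2.18,2.21,
5dhmC,1.79,1.76,1.99,2.00,1.96,1.95,2.25,2.19,
5caC,2.29,2.24,2.62,2.59,1.66,1.62,1.91,2.06,
d_5caC,1.66,1.62,1.90,2.06,1.03,1.00,1.19,1.52,
1mC,1.80,1.84,2.05,2.09,2.64,2.52,2.82,2.74,
1m5mC,1.53,1.60,1.77,1.84,2.49,2.50,2.64,2.70,
1m5hmC,1.67,1.68,1.91,1.92,2.49,2.25,2.80,2.71,
1m5fC,2.26,2.24,2.43,2.44,2.75,2.60,2.91,2.83,
1m5dhmC,1.82,1.79,2.11,2.10,2.12,2.00,2.79,2.60,
1m5caC,2.22,2.15,2.44,2.56,2.64,2.52,2.82,2.74,
d_1m5caC,1.66,1.74,2.25,2.23,1.09,1.34,2.09,1.91,
U,2.25,2.12,2.44,2.36,1.72,1.68,1.97,1.94,1.34
T,1.92,1.81,2.15,2.11,1.55,1.46,1.82,1.54,
5hmU,2.08,1.96,2.47,2.31,1.62,1.52,1.91,1.80,
5fU,2.47,2.42,2.76,3.09,1.67,1.77,1.92,1.93,
5dhmU,2.25,2.15,2.55,2.50,1.63,2.01,1.95,2.32,
5caU,2.75,2.57,3.03,2.89,1.75,1.76,1.95,1.99,
d_5caU,1.73,1.73,1.77,1.77,0.73,0.91,0.69,0.86,
1mU,2.09,2.00,2.29,2.25,2.21,2.12,2.48,2.45,
1mT,1.73,1.74,1.98,2.03,1.76,1.89,2.26,2.22,
1m5hmU,1.97,1.94,2.27,2.26,2.03,1.94,2.30,2.19,
1m5fU,2.39,2.33,2.53,2.53,2.27,2.13,2.59,2.51,
1m5dhmU,2.10,2.07,2.38,2.46,1.89,1.94,2.31,2.27,
1m5caU,2.55,2.48,2.69,2.69,1.86,1.81,2.47,2.50,
d_1m5caU,1.67,1.65,2.10,2.13,0.98,0.99,1.88,1.94,
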