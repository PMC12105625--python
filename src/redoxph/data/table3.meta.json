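{
  "title": "Aqueous oxidation potentials: experimental vs M1 (and M2 for X/hX), V vs SHE",
  "units": {"SMD_DFT": "V", "SMD_DFT_H2O": "V", "SMD_CBS": "V", "SMD_CBS_H2O": "V", "experiment": "V"},
  "kinds": {
    "m1": "plain M1 value compared to experiment",
    "m2": "bold row: Henderson-Hasselbalch M2 average using experimental pKa",
    "m1_raw": "raw M1 component (neutral or d_ deprotonated pathway) feeding the m2 rows"
  },
  "footnote_mole_fractions": {
    "pH7": {"X": 0.76, "d_X": 0.24, "hX": 0.99, "d_hX": 0.01},
    "pH9": {"hX": 0.44, "d_hX": 0.56}
  },
  "printed_metrics": {
    "SMD_DFT": {"r_squared": 0.02, "slope": 0.06, "intercept": 1.17, "mse": 0.27, "mue": 0.38, "rmse": 0.47},
    "SMD_DFT_H2O": {"r_squared": 0.04, "slope": 0.10, "intercept": 1.11, "mse": 0.22, "mue": 0.32, "rmse": 0.41},
    "SMD_CBS": {"r_squared": 0.02, "slope": 0.08, "intercept": 1.12, "mse": 0.51, "mue": 0.52, "rmse": 0.63},
    "SMD_CBS_H2O": {"r_squared": 0.05, "slope": 0.11, "intercept": 1.07, "mse": 0.48, "mue": 0.48, "rmse": 0.58}
  }
}
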