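{
  "title": "Aqueous oxidation potentials at pH 7: M3 and M4 vs experiment, V vs SHE",
  "units": {"experiment": "V", "all model columns": "V"},
  "printed_metrics": {
    "M3_SMD_DFT": {"r_squared": 0.58, "slope": 0.59, "intercept": 0.52, "mse": -0.05, "mue": 0.12, "rmse": 0.14},
    "M4_SMD_DFT": {"r_squared": 0.81, "slope": 0.56, "intercept": 0.31, "mse": 0.38, "mue": 0.38, "rmse": 0.40},
    "M3_SMD_DFT_H2O": {"r_squared": 0.67, "slope": 0.60, "intercept": 0.50, "mse": -0.04, "mue": 0.10, "rmse": 0.13},
    "M4_SMD_DFT_H2O": {"r_squared": 0.88, "slope": 0.60, "intercept": 0.30, "mse": 0.32, "mue": 0.32, "rmse": 0.34},
    "M3_SMD_CBS": {"r_squared": 0.59, "slope": 0.65, "intercept": 0.34, "mse": 0.12, "mue": 0.14, "rmse": 0.17},
    "M4_SMD_CBS": {"r_squared": 0.85, "slope": 0.59, "intercept": 0.15, "mse": 0.58, "mue": 0.58, "rmse": 0.59},
    "M3_SMD_CBS_H2O": {"r_squared": 0.68, "slope": 0.67, "intercept": 0.31, "mse": 0.14, "mue": 0.16, "rmse": 0.18},
    "M4_SMD_CBS_H2O": {"r_squared": 0.93, "slope": 0.60, "intercept": 0.14, "mse": 0.56, "mue": 0.56, "rmse": 0.57}
  },
  "notes": "1mInd has no acidic proton, so M3/M4 are not applicable and its row is blank. Printed slope/MSE/RMSE were evidently computed on unrounded values; only R^2 recomputes exactly from the rounded columns."
}
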