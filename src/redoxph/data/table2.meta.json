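{
  "title": "Gas-phase AIE and acetonitrile oxidation potentials: computed (M1) vs experiment",
  "units": {
    "AIE_DFT": "eV", "AIE_CBS": "eV", "AIE_exp": "eV",
    "Eac_SMD_DFT": "V vs SCE", "Eac_SMD_CBS": "V vs SCE", "Eac_exp": "V vs SCE"
  },
  "censoring": "uracil Eac_exp is a lower bound printed '>2.15'",
  "printed_metrics": {
    "AIE_DFT": {"r_squared": 0.98, "slope": 0.97, "intercept": 0.45, "mse": -0.25, "mue": 0.25, "rmse": 0.26},
    "AIE_CBS": {"r_squared": 0.99, "slope": 1.02, "intercept": -0.23, "mse": 0.03, "mue": 0.04, "rmse": 0.06},
    "Eac_SMD_DFT": {"r_squared": 0.98, "slope": 0.95, "intercept": 0.32, "mse": -0.26, "mue": 0.26, "rmse": 0.27},
    "Eac_SMD_CBS": {"r_squared": 0.96, "slope": 1.02, "intercept": -0.02, "mse": -0.01, "mue": 0.05, "rmse": 0.08}
  },
  "notes": "Printed AIE_exp for uracil (8.68 eV) disagrees with the 9.32 eV of table1; both are transcribed as printed, so the gas-phase AIE regression rows are informational only."
}
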