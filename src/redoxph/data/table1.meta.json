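{
  "title": "Experimental oxidation potentials, pKa values and gas-phase AIE of the benchmark compounds",
  "units": {
    "AIE_eV": "eV",
    "Eox_ac_V": "V vs SCE (acetonitrile)",
    "Eox_aq_V": "V vs SHE (aqueous)",
    "Eox_aq2_V": "V vs SHE (aqueous, second measurement at pH2)",
    "pKa_plus1_r": "pKa of the protonated (q=+1) reduced species",
    "pKa_zero_r": "pKa of the neutral (q=0) reduced species",
    "pKa_minus1_r": "pKa of the deprotonated (q=-1) reduced species"
  },
  "censoring": "entries prefixed '>' are lower bounds (e.g. uracil Eox_ac '>2.15', pKa '>13.0')",
  "notes": "Eox_aq2_V/pH2 hold the second aqueous measurement printed for G, C, U and hX."
}
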