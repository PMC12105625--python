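{
  "title": "Absolute computed oxidation potentials of cytosine/uracil derivatives in water (M1 and M4 at pH 7), V vs SHE",
  "units": {"all model columns": "V", "experiment": "V"},
  "notes": "d_ rows are the deprotonated pathway (R. | R-) of the corresponding acid. Experimental anchors: C 1.44 V and U 1.34 V (extrapolated assuming 60 mV per pH unit)."
}
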