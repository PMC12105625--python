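{
  "title": "Linearly adjusted M4 (pH 7) oxidation potentials in water, V vs SHE",
  "units": {"all columns": "V"},
  "construction": "slope factor 0.60 from the M4 benchmark regression; cytosine derivatives anchored to C = 1.44 V, uracil derivatives anchored to U = 1.34 V; anchor rows flagged is_anchor",
  "notes": "For the strongly acidic 5ca compounds the deprotonated-pathway (d_) rows carry the appropriate prediction at pH 7."
}
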