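{
  "provenance": "synthetic default: per-nucleus base coefficients chosen so that carbon shifts dominate, protons contribute least; combination-specific overrides empty. Replace with optimized per-combination coefficients for production use.",
  "base": {"CA": 1.0, "C": 0.9, "CB": 0.85, "N": 0.45, "H": 0.25, "HA": 0.6},
  "combinations": {},
  "unreliable_combinations": []
}
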