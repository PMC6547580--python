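{
  "correlation_method": "spearman",
  "ambiguity_threshold": 0.1,
  "proliferation_genes": [
    "CCNB1", "UBE2C", "BIRC5", "KNTC2", "CDC20", "PTTG1", "RRM2", "MKI67",
    "TYMS", "CEP55", "CDCA1"
  ],
  "ror_s": {
    "weights": {"Basal": 0.05, "Her2": 0.12, "LumA": -0.34, "LumB": 0.23, "Normal": 0.0},
    "proliferation_weight": 0.0,
    "rescale_low": -0.74,
    "rescale_high": 0.74
  },
  "ror_ps": {
    "weights": {"Basal": 0.05, "Her2": 0.11, "LumA": -0.24, "LumB": 0.07, "Normal": 0.0},
    "proliferation_weight": 0.17,
    "rescale_low": -0.81,
    "rescale_high": 0.81
  },
  "risk_cutoffs": {
    "ror_s": [29.0, 53.0],
    "ror_ps": [23.0, 52.0]
  },
  "tie_break": ["Basal", "Her2", "LumA", "LumB", "Normal"]
}
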