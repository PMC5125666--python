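{
  "description": "Published reference summaries of the FEST order-correct covariate regressions for the combined middle-to-older listener groups: model R-squared and per-predictor squared semi-partial correlations, one model per sequence coherence condition. Entries printed below three-decimal precision in the original report are stored as 0.0.",
  "predictors": ["Age", "PTA", "QuickSIN", "SPIN_high", "SPIN_low", "MoCA", "LNS", "RS"],
  "coherent": {
    "r2": 0.603,
    "squared_semi_partial": {
      "Age": 0.0,
      "PTA": 0.034,
      "QuickSIN": 0.008,
      "SPIN_high": 0.002,
      "SPIN_low": 0.060,
      "MoCA": 0.150,
      "LNS": 0.031,
      "RS": 0.0
    },
    "below_precision": ["Age", "RS"]
  },
  "incoherent": {
    "r2": 0.645,
    "squared_semi_partial": {
      "Age": 0.0,
      "PTA": 0.004,
      "QuickSIN": 0.007,
      "SPIN_high": 0.019,
      "SPIN_low": 0.022,
      "MoCA": 0.120,
      "LNS": 0.117,
      "RS": 0.004
    },
    "below_precision": ["Age"]
  }
}
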