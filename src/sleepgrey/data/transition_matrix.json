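{
  "comment": "Default stage-to-stage transition probabilities of the synthetic hypnogram Markov chain. Rows/columns in canonical order W, N1, N2, N3, REM; rows sum to 1. Built by detailed balance so the stationary distribution is exactly (0.15, 0.10, 0.45, 0.15, 0.15) with every self-transition >= 0.85 for realistic 30-s-epoch stage persistence.",
  "stages": ["W", "N1", "N2", "N3", "R"],
  "stationary": [0.15, 0.10, 0.45, 0.15, 0.15],
  "matrix": [
    [0.926666666667, 0.033333333333, 0.010000000000, 0.000000000000, 0.030000000000],
    [0.050000000000, 0.850000000000, 0.080000000000, 0.000000000000, 0.020000000000],
    [0.003333333333, 0.017777777778, 0.946666666667, 0.023333333333, 0.008888888889],
    [0.000000000000, 0.000000000000, 0.070000000000, 0.930000000000, 0.000000000000],
    [0.030000000000, 0.013333333333, 0.026666666667, 0.000000000000, 0.930000000000]
  ]
}
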