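{
  "comment": "Given that a simulated scorer errs on an epoch of true stage <row>, probability of each wrongly assigned stage <column>. Mass concentrates on stages adjacent in depth (W-N1, N1-N2, N2-N3, N2-REM), where human scoring confusions cluster. Diagonal is zero; rows sum to 1.",
  "stages": ["W", "N1", "N2", "N3", "R"],
  "kernel": [
    [0.00, 0.70, 0.15, 0.05, 0.10],
    [0.45, 0.00, 0.40, 0.05, 0.10],
    [0.10, 0.35, 0.00, 0.30, 0.25],
    [0.05, 0.10, 0.80, 0.00, 0.05],
    [0.15, 0.30, 0.45, 0.10, 0.00]
  ]
}
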