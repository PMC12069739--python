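{
  "comment": "Relative spectral band-power weights (delta 0.5-4 Hz, theta 4-8, alpha 8-12, sigma 12-16, beta 16-32) and overall amplitude scale per sleep stage for the synthetic PSG generator. Profiles are spectrally separable caricatures, not physiologically faithful EEG.",
  "bands_hz": [[0.5, 4.0], [4.0, 8.0], [8.0, 12.0], [12.0, 16.0], [16.0, 32.0]],
  "stages": ["W", "N1", "N2", "N3", "R"],
  "weights": [
    [0.15, 0.15, 0.40, 0.10, 0.20],
    [0.20, 0.45, 0.15, 0.10, 0.10],
    [0.30, 0.25, 0.10, 0.25, 0.10],
    [0.65, 0.15, 0.08, 0.07, 0.05],
    [0.20, 0.35, 0.10, 0.05, 0.30]
  ],
  "amplitude_scale": [1.0, 0.9, 1.0, 1.3, 0.7],
  "broadband_level": 0.05
}
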