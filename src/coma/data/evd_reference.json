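{
  "lambda_g": 0.19298282430244407,
  "mu": 22.01235020385431,
  "K_g": 0.0017491431820155562,
  "search_space": 40000.0,
  "fit_threshold": 36.10314353550376,
  "stderr_lambda": 0.007169246887040443,
  "stderr_mu": 0.5612680388631373,
  "n_scores": 713,
  "provenance": "synthetic calibration: all unordered pairs of 150 unrelated fixture profiles (200 positions x 50 sequences), seed 12345"
}
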