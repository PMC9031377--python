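# Single-trace example: one clean synthetic curve, default sharpening settings.
model:
  ftrue_ghz: 2.25
  amplitude_db: 18.0
  offset_db: 2.0
  sigma_left_ghz: 0.07
  sigma_right_ghz: 0.10
  fmin_ghz: 2.0
  fmax_ghz: 3.0
sharpen:
  alpha: 0.1
  beta: 0.05
  nt: 512
  n_hat_f: 512
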