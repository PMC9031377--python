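# Monte Carlo benchmark with every parameter random (f_true range in GHz).
model:
  amplitude_db: 18.0
  offset_db: 2.0
  sigma_left_ghz: 0.07
  sigma_right_ghz: 0.10
  fmin_ghz: 2.0
  fmax_ghz: 3.0
monte_carlo:
  n_reps: 500
  ranges:
    alpha: [0.1, 0.9]
    beta: [0.05, 0.45]
    nf: [100, 900]
    nt: [512, 4608]
    n_hat_f: [512, 4608]
    f_true: [2.25, 2.75]
  algorithms: [single_step, iterative, music]
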