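{
  "comment": "Default per-feature-class regularization scalars, linearly interpolated by presence sample size (clamped at the table ends). These are the sample-size-interpolated defaults popularized by the standard maximum-entropy SDM implementations.",
  "linear_quadratic_product": {"sample_sizes": [0, 10, 30, 100], "betas": [1.0, 1.0, 0.2, 0.05]},
  "hinge": {"sample_sizes": [0, 1], "betas": [0.5, 0.5]}
}
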