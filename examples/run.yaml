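# Full end-to-end run for the ester pair EA+BA at the benchmark seeds.
generator:
  pair: [EA, BA]
  seed: 42
  rho_max: 0.35
  shape_p: 1.0
  noise_sigma: 0.3
  n_samples: 30
  x_levels: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
  total_lnoav_range: [3.0, 10.0]
  min_oi_sum: 2.0
  oi_clip: [0.0, 8.0]
  interaction: ratio_kernel
split:
  train_fraction: 0.7
  seed: 7
model:
  cv_folds: 10
  seed: 11
surface:
  resolution: 50
  min_oi_sum: 2.0
output_dir: results/ea_ba
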