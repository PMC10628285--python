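# Full pipeline defaults. CLI flags and user YAML override these values.
simulate:
  n_rows: 8
  n_cols: 16
  pitch_mm: 1.33
  mask_corners: 0
  fs: 2000.0
  n_blocks: 3
  source_sigma_mm: 2.5
  source_gain: 1.0
  onset_lead_s: 0.3
  noise_corr_length_mm: 1.2
  leak_gain: 0.0
preprocess:
  impedance_max_kohm: 1000.0      # 1 MOhm
  log_rms_mad_factor: 3.0
  epoch_rms_factor: 10.0
  hg_band_hz: [70.0, 150.0]
  n_hg_bands: 8
  lfs_band_hz: [1.0, 30.0]
  fs_env: 200.0
  baseline_s: 0.5                 # pre-stimulus baseline window length
  window_s: [-0.5, 0.5]           # analysis window around alignment event
metrics:
  spect_window_s: 0.5
  spect_step_s: 0.05
  freq_smoothing_hz: 10.0         # +/- 5 Hz half-bandwidth, 4 tapers
  esnr_window_s: [-0.5, 0.5]
  esnr_band_hz: [70.0, 150.0]
  esnr_convention: mean           # 'mean' (ratio==1 -> 0 dB) or 'sum' (literal)
  n_permutations: 10000
  fdr_alpha: 0.05
  contamination_window_s: 0.2
statespace:
  var_frac: 0.8
  perplexity: 30
  n_shuffles: 1000
  poisson_disc_factor: 3.5
  n_subsamples: 50
  fractions: [1.0, 0.5, 0.25, 0.125]
decode:
  outer_folds: 20
  inner_folds: 20
  var_grid: [0.2, 0.4, 0.6, 0.8, 0.9, 0.99]
  chance: 0.111111
  temporal_window_s: 0.2
  temporal_step_s: 0.01
  temporal_range_s: [-1.0, 1.0]
seq2seq:
  kernel_width_s: 0.05
  hop_s: 0.05
  n_kernels: 32
  n_rnn_units: 64
  l2_penalty: 0.0001
  learning_rate: 0.001
  n_epochs: 800
  test_fraction: 0.2
  tuning:
    n_combinations: 200
    cv_folds: 10
    cv_repeats: 3
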