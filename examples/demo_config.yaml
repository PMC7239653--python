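# Demo configuration for `odmap report`.
# Runs the full simulate -> analyze -> summarize pipeline on small synthetic
# datasets in well under five minutes on one CPU.
seed: 1

imaging:
  n_animals: 3
  odi_before: 0.30       # naive contralateral bias
  odi_after: 0.10        # after depression-type conditioning
  shape: [48, 48]
  radius: 16
  duration_s: 100.0
  frame_rate_hz: 10.0
  stim_freq_hz: 0.12     # 12 integer cycles in 100 s
  noise_sd: 2.0e-4
  roi_fraction: 0.3
  sigma_px: 1.0
  n_bins: 50

quantal:
  n_cells: 3
  n_sweeps: 30
  spont_rate: 1.0
  evoked_rate: 7.0       # post-window rate = 1 + 7 = 8 events/s
  spont_amp_mean: 12.0
  evoked_amp_mean: 18.0
  noise_rms: 1.5

stdp:
  baseline_slope: 2.0
  post_ratios: [0.6, 1.0, 1.235]
  slope_noise_frac: 0.05
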