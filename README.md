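# odmap

Measurement pipelines for neuromodulator-gated ocular-dominance plasticity
experiments, with seeded synthetic-data generators so every stage is testable
without raw recordings:

- **Intrinsic-signal imaging** — per-pixel Fourier extraction of the response
  magnitude at a periodic bar-sweep stimulus frequency, drift-direction
  averaging, 5×5 Gaussian smoothing, binocular ROI at 30% of the smoothed
  ipsilateral peak, per-eye ROI amplitudes and the ocular dominance index
  (mean pixelwise `(C−I)/(C+I)` with its pixel histogram).
- **Sr²⁺-desynchronized quantal EPSC analysis** — robust baseline RMS
  estimation, event detection at 3×RMS with a 3 ms rise-time cut, 400 ms
  pre/post stimulation windows, and the spontaneous-corrected evoked quantal
  amplitude `(post_amp·post_freq − pre_amp·pre_freq)/(post_freq − pre_freq)`.
- **STDP quantification** — EPSP onset detection, initial slope (first 2 ms)
  by least squares, 30-sweep baseline, and the endpoint plasticity magnitude
  as percent of baseline.
- **Session reporting** — before/after deltas per animal, group mean ± s.e.m.
  summaries (with a routine paired Wilcoxon wrapper), and a deterministic
  end-to-end pipeline driver.

## Layout

| module | contents |
| --- | --- |
| `odmap.synthetic` | seeded generators + ground-truth containers (`ImagingTruth`, `EphysTruth`) |
| `odmap.imaging` | `fourier_response_map`, `average_directions`, `smooth_map`, `define_binocular_roi`, `compute_odi`, `analyze_session` |
| `odmap.quantal` | `estimate_rms_noise`, `detect_events`, `window_stats`, `evoked_quantal_amplitude`, `analyze_cell` |
| `odmap.stdp` | `epsp_onset`, `epsp_slope`, `baseline_slope`, `plasticity_magnitude`, `analyze_plasticity` |
| `odmap.reporting` | `compare_sessions`, `summarize_group`, `run_pipeline` |
| `odmap.io` | TIFF/HDF5 stack + JSON sidecar, sweep-set HDF5, CSV tables |
| `odmap.benchmarks` | seeded parameter-recovery runs used by the acceptance checks |

## CLI

```sh
# synthetic data with known ground truth
odmap simulate --kind imaging --out data/session --seed 1 --odi 0.3
odmap simulate --kind quantal --out data/cell --seed 1

# analysis
odmap map data/session/contra_90.h5 --out contra_90_map.h5
odmap odi data/session --out session.csv --roi-fraction 0.3 --bins 50
odmap compare before.csv after.csv --out delta.csv
odmap quantal data/cell/sweeps.h5 --out cell.csv --threshold-mult 3
odmap stdp data/epsp_sweeps.h5 --out plasticity.csv --n-baseline 30

# full pipeline from a config file
odmap report examples/demo_config.yaml --out results/demo
```

Stacks are multi-page TIFF or HDF5 with a JSON sidecar
(`frame_rate_hz`, `stim_freq_hz`, `eye`, `direction_deg`); current sweeps are
HDF5 (`sweeps` dataset in pA, attributes `sampling_rate_hz`, `stim_onset_s`,
test-pulse window); the same schemas accept real acquisitions.

## Notes

- Magnitudes are reported as fractional reflectance change ×10⁴ throughout.
- The bar-sweep temporal frequency is not fixed by the experimental
  description; the generator default is 0.12 Hz (36 integer cycles in a
  300 s acquisition) and is configurable everywhere.
- All generators are bit-reproducible under a fixed seed; pipeline reruns
  with the same config and seed produce byte-identical reports.
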