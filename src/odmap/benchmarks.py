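"""Seeded parameter-recovery runs used by the acceptance checks.

Each function generates synthetic data with known ground truth, runs the
corresponding analysis pipeline from scratch, and returns a tidy per-item
frame; callers aggregate and assert.  Kept in the package (rather than in
the test suite) so the standalone acceptance report exercises exactly the
same code paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import imaging, quantal, stdp, synthetic


def fourier_oracle_run(n_draws: int = 20, seed: int = 0) -> pd.DataFrame:
    """Noise-free integer-cycle cosine stacks vs the closed-form amplitude.

    Draws random (amplitude, frequency, phase); frequency is an exact DFT
    bin (k cycles over the acquisition), so the recovered magnitude must be
    amplitude x 1e4 to near machine precision.
    """
    rng = np.random.default_rng(seed)
    duration, frame_rate = 300.0, 30.0
    rows = []
    for _ in range(n_draws):
        amp = rng.uniform(5e-5, 5e-4)
        k = int(rng.integers(2, 200))  # integer cycles -> exact bin
        freq = k / duration
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(int(duration * frame_rate)) / frame_rate
        trace = 1.0 + amp * np.cos(2 * np.pi * freq * t + phase)
        frames = np.broadcast_to(trace[:, None, None], (len(t), 2, 2)).copy()
        stack = imaging.IntrinsicStack(
            frames=frames, frame_rate=frame_rate, stim_freq=freq,
            eye="contra", direction=90.0,
        )
        mag = imaging.fourier_response_map(stack).magnitude
        rel_err = float(np.max(np.abs(mag - amp * 1e4)) / (amp * 1e4))
        rows.append({"amplitude": amp, "freq_hz": freq, "phase": phase,
                     "rel_error": rel_err})
    return pd.DataFrame(rows)


def odi_recovery_run(
    n_sessions: int = 100,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    radius: float = 20.0,
    duration: float = 300.0,
    frame_rate: float = 30.0,
    stim_freq: float = 0.12,
    noise_sd: float = 1e-3,
    odi_range: tuple[float, float] = (-0.1, 0.5),
    dtype=np.float32,
) -> pd.DataFrame:
    """Full simulate -> map -> smooth -> ROI -> ODI recovery per session."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sessions):
        true_odi = float(rng.uniform(*odi_range))
        truth = synthetic.ImagingTruth.from_odi(
            true_odi, shape=shape, radius=radius, noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31)),
        )
        stacks = synthetic.gen_session(
            truth, duration=duration, frame_rate=frame_rate,
            stim_freq=stim_freq, dtype=dtype,
        )
        analysis = imaging.analyze_session(stacks.values())
        res = analysis.odi_result
        # expected amplitude over the recovered ROI: the noise-free pipeline
        # output, i.e. the smoothed truth map averaged over the same mask
        expected = {}
        for eye in imaging.EYES:
            sm = imaging.smooth_map(
                imaging.ResponseMap(truth.amp_map(eye) * 1e4, eye=eye)
            )
            expected[eye] = float(sm.magnitude[analysis.roi.mask].mean())
        rows.append(
            {
                "session": i,
                "true_odi": true_odi,
                "odi": res.odi,
                "amp_contra": res.amp_contra,
                "amp_ipsi": res.amp_ipsi,
                "true_amp_contra": expected["contra"],
                "true_amp_ipsi": expected["ipsi"],
                "n_pixels": res.n_pixels,
            }
        )
        del stacks
    return pd.DataFrame(rows)


def quantal_recovery_run(
    n_cells: int = 50,
    seed: int = 0,
    n_sweeps: int = 60,
    noise_rms: float = 2.0,
    recall_min_mult: float = 5.0,
) -> pd.DataFrame:
    """Per-cell quantal pipeline recovery against generator ground truth.

    Cells use the reference truth (spontaneous 12 pA at 1/s, evoked 18 pA
    raising the post-window rate to 8/s).  ``recall`` is the detection
    recall for true events >= ``recall_min_mult`` x the true noise RMS,
    excluding events in the (undetectable by design) test-pulse window.
    """
    rows = []
    for i in range(n_cells):
        truth = synthetic.EphysTruth(noise_rms=noise_rms, seed=seed * 100_003 + i)
        sweeps, truth = synthetic.gen_sr_sweeps(n_sweeps, truth)
        est = quantal.analyze_cell(sweeps)
        recall = float("nan")
        if est.included:
            events = quantal.detect_events(sweeps, est.rms_noise)
            recall = synthetic.detection_recall(
                truth.event_log, events,
                min_amplitude=recall_min_mult * truth.noise_rms,
            )
        rows.append(
            {
                "cell": i,
                "rms_noise": est.rms_noise,
                "included": est.included,
                "exclusion_reason": est.exclusion_reason,
                "evoked_amp": est.evoked_amp,
                "true_corrected_amp": truth.true_corrected_amp,
                "recall": recall,
            }
        )
    return pd.DataFrame(rows)


def stdp_recovery_run(
    ratios=(0.6, 1.0, 1.235),
    n_seeds: int = 50,
    seed: int = 0,
    slope_noise_frac: float = 0.05,
    baseline_slope: float = 2.0,
) -> pd.DataFrame:
    """End-to-end plasticity recovery for each post/baseline slope ratio."""
    rows = []
    for ratio in ratios:
        for j in range(n_seeds):
            sweeps = synthetic.gen_stdp_sweeps(
                baseline_slope, ratio, slope_noise_frac=slope_noise_frac,
                seed=seed * 100_003 + j,
            )
            _, res = stdp.analyze_plasticity(sweeps)
            rows.append(
                {
                    "post_ratio": ratio,
                    "seed": j,
                    "final_percent": res.final_percent,
                    "expected_percent": 100.0 * ratio,
                }
            )
    return pd.DataFrame(rows)
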