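"""Sr2+-desynchronized quantal EPSC analysis.

Sweeps are 1500 ms voltage-clamp current traces (pA, inward negative) with
stimulation at 700 ms.  Desynchronized events are detected at a threshold of
three times the baseline RMS noise; events with 10-90% rise time > 3 ms and
cells with RMS noise > 2 pA are excluded.  Spontaneous activity in a 400 ms
pre-stimulation window is used to correct the mean amplitude measured in a
400 ms window starting 50 ms after stimulation:

    evoked_amp = (post_amp * post_freq - pre_amp * pre_freq)
                 / (post_freq - pre_freq)

which is exact when post-window events are the union of the spontaneous and
the evoked processes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import NoRateIncreaseError, ParameterError, ValidationError

PRE_WINDOW_LEN = 0.4  # s before stimulation
POST_DELAY = 0.05  # s after stimulation onset
POST_WINDOW_LEN = 0.4  # s
RISE_TIME_MAX_MS = 3.0  # events with slower 10-90% rise are excluded
RMS_CUTOFF_PA = 2.0  # cells noisier than this are excluded

#: columns of the event table produced by :func:`detect_events`
EVENT_COLUMNS = ("sweep_index", "time", "amplitude", "rise_time_ms", "window")


@dataclass(frozen=True)
class SweepSet:
    """Equal-length current sweeps from one cell."""

    sweeps: np.ndarray  # (n_sweeps, n_samples), pA, inward negative
    sampling_rate: float
    stim_onset: float = 0.7
    test_pulse_window: tuple[float, float] = (0.0, 0.1)

    def __post_init__(self) -> None:
        if self.sweeps.ndim != 2 or self.sweeps.shape[0] < 1:
            raise ParameterError("sweeps must be a (n_sweeps, n_samples) array")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        dur = self.sweep_duration
        if not 0 < self.stim_onset < dur:
            raise ParameterError("stim_onset must fall inside the sweep")
        lo, hi = self.test_pulse_window
        if not 0 <= lo < hi <= dur:
            raise ParameterError("test_pulse_window must lie inside the sweep")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def sweep_duration(self) -> float:
        return self.sweeps.shape[1] / self.sampling_rate

    def window_bounds(self, window: str) -> tuple[float, float]:
        """Half-open [start, end) bounds of the 'pre' or 'post' window."""
        if window == "pre":
            return self.stim_onset - PRE_WINDOW_LEN, self.stim_onset
        if window == "post":
            start = self.stim_onset + POST_DELAY
            return start, start + POST_WINDOW_LEN
        raise ParameterError(f"unknown window {window!r}")


@dataclass(frozen=True)
class QuantalEstimate:
    """Per-cell pre/post statistics and the corrected evoked amplitude."""

    pre_amp: float
    pre_freq: float
    post_amp: float
    post_freq: float
    evoked_amp: float
    rms_noise: float
    n_events: int
    included: bool
    exclusion_reason: str  # 'none', 'rms_noise' or 'no_rate_increase'


def estimate_rms_noise(
    sweeps: SweepSet,
    chunk_len: float = 0.05,
    exclude: tuple[float, float] = (0.65, 1.2),
) -> float:
    """Robust RMS of the event-free baseline, in pA.

    The baseline segment excludes the test pulse and the ``exclude`` interval
    around stimulation.  It is split into ``chunk_len`` chunks; each chunk
    contributes the standard deviation of its median-subtracted samples, a
    sweep contributes the median over its chunks, and the cell estimate is
    the median across sweeps.  Taking medians twice makes the estimate
    insensitive to sparse synaptic events in the baseline.
    """
    fs = sweeps.sampling_rate
    n = sweeps.sweeps.shape[1]
    t = np.arange(n) / fs
    tp_lo, tp_hi = sweeps.test_pulse_window
    keep = ~(((t >= tp_lo) & (t < tp_hi + 0.01)) | ((t >= exclude[0]) & (t < exclude[1])))
    if not keep.any():
        raise ParameterError("no baseline samples outside the excluded windows")
    chunk = max(int(round(chunk_len * fs)), 8)
    per_sweep = []
    for trace in sweeps.sweeps:
        seg = trace[keep]
        n_chunks = len(seg) // chunk
        if n_chunks == 0:
            sds = [float(np.std(seg - np.median(seg)))]
        else:
            blocks = seg[: n_chunks * chunk].reshape(n_chunks, chunk)
            sds = np.std(blocks - np.median(blocks, axis=1, keepdims=True), axis=1)
        per_sweep.append(float(np.median(sds)))
    return float(np.median(per_sweep))


def _interp_crossing(t0, t1, v0, v1, level):
    """Time where a linearly interpolated trace crosses ``level`` (v0 >= level >= v1)."""
    if v0 == v1:
        return t0
    return t0 + (t1 - t0) * (v0 - level) / (v0 - v1)


def detect_events(
    sweeps: SweepSet,
    rms: float,
    threshold_mult: float = 3.0,
    smooth_sigma_ms: float = 0.15,
    refractory_ms: float = 2.0,
    rise_time_max_ms: float = RISE_TIME_MAX_MS,
) -> pd.DataFrame:
    """Detect inward desynchronized events above ``threshold_mult * rms``.

    Detection operates on a Gaussian low-pass filtered copy of each sweep
    (sigma ``smooth_sigma_ms``, ~1.2 kHz cutoff at the default).  Candidate
    events are local minima separated by at least ``refractory_ms``; the
    amplitude is the local pre-event baseline (median of the 5 ms preceding
    onset) minus the trace around the peak, and the 10-90% rise time is
    measured on the filtered trace with sub-sample interpolation.  Events
    inside the test-pulse window or with rise time > ``rise_time_max_ms``
    are discarded.

    Returns a :class:`pandas.DataFrame` with columns ``sweep_index``,
    ``time`` (onset, s), ``amplitude`` (pA, positive), ``rise_time_ms`` and
    ``window`` ('pre', 'post' or 'other').
    """
    if rms <= 0:
        raise ParameterError("rms must be positive")
    fs = sweeps.sampling_rate
    if fs < 5000:
        raise ParameterError(f"sampling rate {fs} Hz too low to resolve 1 ms rise")
    threshold = threshold_mult * rms
    sigma = smooth_sigma_ms * 1e-3 * fs
    refractory = max(int(round(refractory_ms * 1e-3 * fs)), 1)
    base_lo = int(round(8e-3 * fs))  # baseline window: [peak-8 ms, peak-3 ms]
    base_hi = int(round(3e-3 * fs))
    half_peak = max(int(round(0.2e-3 * fs)), 1)
    tp_lo, tp_hi = sweeps.test_pulse_window
    pre_lo, pre_hi = sweeps.window_bounds("pre")
    post_lo, post_hi = sweeps.window_bounds("post")

    rows = []
    for si, trace in enumerate(sweeps.sweeps):
        f = ndimage.gaussian_filter1d(trace.astype(float), sigma, mode="nearest")
        # prominence guard: noise dips riding on an event's decay clear the
        # baseline-depth test but have only noise-sized prominence
        peaks, _ = signal.find_peaks(
            -f,
            distance=refractory,
            prominence=threshold,
            wlen=int(round(0.05 * fs)),
        )
        for p in peaks:
            lo = max(p - base_lo, 0)
            hi = max(p - base_hi, lo + 1)
            baseline = float(np.median(f[lo:hi]))
            depth = baseline - float(f[p])
            if depth < threshold:
                continue
            # amplitude: short average around the peak sample suppresses the
            # selection bias of picking the noise minimum
            pk_lo = max(p - half_peak, 0)
            pk_hi = min(p + half_peak + 1, len(f))
            amplitude = baseline - float(f[pk_lo:pk_hi].mean())
            if amplitude < threshold:
                continue
            lvl10 = baseline - 0.1 * depth
            lvl90 = baseline - 0.9 * depth
            # walk back from the peak to the 10% / 90% crossings
            seg = f[lo:p + 1]
            above10 = np.nonzero(seg >= lvl10)[0]
            if len(above10) == 0:
                continue  # no return to baseline inside the search window
            i10 = above10[-1] + lo
            above90 = np.nonzero(seg >= lvl90)[0]
            i90 = above90[-1] + lo if len(above90) else i10
            t10 = _interp_crossing(i10 / fs, (i10 + 1) / fs, f[i10], f[i10 + 1], lvl10)
            t90 = _interp_crossing(i90 / fs, (i90 + 1) / fs, f[i90], f[i90 + 1], lvl90)
            rise_ms = max(t90 - t10, 0.0) * 1e3
            onset = t10
            if rise_ms > rise_time_max_ms:
                continue
            if tp_lo - 0.002 <= onset < tp_hi + 0.005:
                continue
            if pre_lo <= onset < pre_hi:
                window = "pre"
            elif post_lo <= onset < post_hi:
                window = "post"
            else:
                window = "other"
            rows.append((si, onset, amplitude, rise_ms, window))
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def window_stats(
    events: pd.DataFrame,
    window: str,
    n_sweeps: int,
    window_len: float = 0.4,
) -> tuple[float, float]:
    """Mean amplitude and event frequency for one window label.

    Frequency is count / (n_sweeps * window_len).  With zero events the
    amplitude is undefined and returned as NaN.
    """
    if n_sweeps < 1:
        raise ParameterError("n_sweeps must be >= 1")
    sel = events[events["window"] == window]
    freq = len(sel) / (n_sweeps * window_len)
    amp = float(sel["amplitude"].mean()) if len(sel) else float("nan")
    return amp, freq


def evoked_quantal_amplitude(
    pre_amp: float, pre_freq: float, post_amp: float, post_freq: float
) -> float:
    """Spontaneous-corrected mean amplitude of the evoked events (pA).

    Computes ``(post_amp*post_freq - pre_amp*pre_freq) / (post_freq - pre_freq)``.
    Raises :class:`NoRateIncreaseError` when ``post_freq <= pre_freq``.
    """
    if pre_freq < 0 or post_freq < 0:
        raise ParameterError("frequencies must be non-negative")
    if post_freq <= pre_freq:
        raise NoRateIncreaseError(
            f"post rate {post_freq:.3g}/s does not exceed pre rate {pre_freq:.3g}/s"
        )
    pre_contrib = pre_amp * pre_freq if pre_freq > 0 else 0.0
    return (post_amp * post_freq - pre_contrib) / (post_freq - pre_freq)


def analyze_cell(
    sweeps: SweepSet,
    threshold_mult: float = 3.0,
    rms_cutoff: float = RMS_CUTOFF_PA,
    **detect_kwargs,
) -> QuantalEstimate:
    """Full per-cell pipeline with the stated exclusion rules."""
    rms = estimate_rms_noise(sweeps)
    if rms > rms_cutoff:
        return QuantalEstimate(
            pre_amp=float("nan"), pre_freq=float("nan"),
            post_amp=float("nan"), post_freq=float("nan"),
            evoked_amp=float("nan"), rms_noise=rms, n_events=0,
            included=False, exclusion_reason="rms_noise",
        )
    events = detect_events(sweeps, rms, threshold_mult=threshold_mult, **detect_kwargs)
    pre_amp, pre_freq = window_stats(events, "pre", sweeps.n_sweeps)
    post_amp, post_freq = window_stats(events, "post", sweeps.n_sweeps)
    if pre_freq == 0:
        pre_amp = 0.0  # no spontaneous contribution to subtract
    try:
        evoked = evoked_quantal_amplitude(pre_amp, pre_freq, post_amp, post_freq)
    except NoRateIncreaseError:
        return QuantalEstimate(
            pre_amp=pre_amp, pre_freq=pre_freq, post_amp=post_amp,
            post_freq=post_freq, evoked_amp=float("nan"), rms_noise=rms,
            n_events=len(events), included=False,
            exclusion_reason="no_rate_increase",
        )
    return QuantalEstimate(
        pre_amp=pre_amp, pre_freq=pre_freq, post_amp=post_amp,
        post_freq=post_freq, evoked_amp=evoked, rms_noise=rms,
        n_events=len(events), included=True, exclusion_reason="none",
    )
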