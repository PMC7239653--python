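"""EPSP initial-slope quantification for plasticity experiments.

Synaptic strength is the initial slope (first 2 ms) of the evoked EPSP.
Sweeps are acquired every 20 s; the baseline is the mean slope of 30
consecutive sweeps before the induction/drug mark, and the plasticity
magnitude is the endpoint-window mean slope expressed as a percentage of
that baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import NoEpspError, ParameterError, ValidationError

ONSET_LATENCY_MAX_MS = 4.0  # monosynaptic inclusion bound; slower onsets warn
ONSET_SEARCH_MS = 10.0
SLOPE_WINDOW_MS = 2.0


@dataclass(frozen=True)
class EpspSweep:
    """One current-clamp voltage sweep (mV)."""

    voltage: np.ndarray
    sampling_rate: float
    stim_time: float
    acquisition_time: float  # s relative to pairing/drug mark; negative = baseline

    def __post_init__(self) -> None:
        if self.voltage.ndim != 1:
            raise ParameterError("voltage must be 1-D")
        if self.sampling_rate < 5000:
            raise ParameterError("sampling_rate must be >= 5 kHz")
        if not 0 <= self.stim_time < len(self.voltage) / self.sampling_rate:
            raise ParameterError("stim_time must fall inside the trace")


@dataclass(frozen=True)
class SlopeSeries:
    """Initial slopes of one pathway over the experiment."""

    times: np.ndarray  # minutes relative to pairing
    slopes: np.ndarray  # mV/ms
    pathway: str = "P1"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.slopes):
            raise ParameterError("times and slopes must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.slopes)):
            raise ParameterError("slopes must be finite")


@dataclass(frozen=True)
class PlasticityResult:
    baseline_mean: float  # mV/ms
    final_percent: float  # endpoint mean as % of baseline
    n_baseline: int
    endpoint_window: tuple[float, float]  # minutes
    n_endpoint: int


def epsp_onset(
    sweep: EpspSweep,
    artifact_blank_ms: float = 0.3,
    sustain_ms: float = 0.5,
) -> float:
    """Detect the EPSP onset time (s) after the stimulus.

    Onset is the first time after ``stim_time + artifact_blank_ms`` where the
    voltage exceeds the pre-stimulus baseline mean + 2 SD and stays above it
    for at least ``sustain_ms``.  Latencies above 4 ms draw a warning (the
    recordings target monosynaptic responses); no crossing within 10 ms
    raises :class:`NoEpspError`.
    """
    fs = sweep.sampling_rate
    i_stim = int(round(sweep.stim_time * fs))
    if i_stim < 2:
        raise ParameterError("need pre-stimulus samples to estimate the baseline")
    base = sweep.voltage[:i_stim]
    mu = float(base.mean())
    sd = float(base.std())
    thr = mu + 2.0 * sd
    i_start = i_stim + int(round(artifact_blank_ms * 1e-3 * fs))
    i_stop = i_stim + int(round(ONSET_SEARCH_MS * 1e-3 * fs))
    i_stop = min(i_stop, len(sweep.voltage))
    sustain = max(int(round(sustain_ms * 1e-3 * fs)), 1)
    seg = sweep.voltage[i_start:i_stop]
    above = seg > thr
    # first index where `sustain` consecutive samples are above threshold
    run = 0
    onset_idx = None
    for j, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= sustain:
            onset_idx = j - sustain + 1
            break
    if onset_idx is None:
        raise NoEpspError(
            f"no sustained crossing of baseline+2SD within {ONSET_SEARCH_MS} ms"
        )
    onset = (i_start + onset_idx) / fs
    latency_ms = (onset - sweep.stim_time) * 1e3
    if latency_ms > ONSET_LATENCY_MAX_MS:
        warnings.warn(
            f"EPSP onset latency {latency_ms:.2f} ms exceeds "
            f"{ONSET_LATENCY_MAX_MS} ms (non-monosynaptic?)",
            stacklevel=2,
        )
    return onset


def epsp_slope(sweep: EpspSweep, onset: float) -> float:
    """Least-squares slope (mV/ms) over [onset, onset + 2 ms]."""
    fs = sweep.sampling_rate
    i0 = int(round(onset * fs))
    i1 = i0 + int(round(SLOPE_WINDOW_MS * 1e-3 * fs)) + 1
    if i1 > len(sweep.voltage):
        raise ParameterError("slope window truncated by the end of the trace")
    t_ms = np.arange(i0, i1) / fs * 1e3
    v = sweep.voltage[i0:i1]
    slope, _ = np.polyfit(t_ms, v, 1)
    return float(slope)


def slope_series(sweeps, pathway: str = "P1") -> SlopeSeries:
    """Measure onset and initial slope for every sweep of one pathway."""
    pairs = []
    for sw in sweeps:
        onset = epsp_onset(sw)
        pairs.append((sw.acquisition_time / 60.0, epsp_slope(sw, onset)))
    pairs.sort(key=lambda p: p[0])
    times = np.array([p[0] for p in pairs])
    slopes = np.array([p[1] for p in pairs])
    return SlopeSeries(times=times, slopes=slopes, pathway=pathway)


def baseline_slope(series: SlopeSeries, n: int = 30, mark_min: float = 0.0) -> float:
    """Mean of the last ``n`` slopes acquired before ``mark_min`` (minutes)."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    pre = series.slopes[series.times < mark_min]
    if len(pre) < n:
        raise ValidationError(
            f"only {len(pre)} baseline sweeps before t={mark_min} min; need {n}"
        )
    return float(pre[-n:].mean())


def plasticity_magnitude(
    series: SlopeSeries,
    baseline: float,
    endpoint_window: tuple[float, float] = (25.0, 30.0),
    n_baseline: int = 30,
    min_endpoint_sweeps: int = 3,
) -> PlasticityResult:
    """Endpoint-window mean slope as a percentage of the baseline slope."""
    if baseline <= 0:
        raise ParameterError("baseline slope must be positive")
    lo, hi = endpoint_window
    sel = series.slopes[(series.times >= lo) & (series.times <= hi)]
    if len(sel) < min_endpoint_sweeps:
        raise ValidationError(
            f"{len(sel)} sweeps in the endpoint window {endpoint_window}; "
            f"need >= {min_endpoint_sweeps}"
        )
    return PlasticityResult(
        baseline_mean=baseline,
        final_percent=100.0 * float(sel.mean()) / baseline,
        n_baseline=n_baseline,
        endpoint_window=(float(lo), float(hi)),
        n_endpoint=len(sel),
    )


def analyze_plasticity(
    sweeps,
    pathway: str = "P1",
    n_baseline: int = 30,
    endpoint_window: tuple[float, float] = (25.0, 30.0),
) -> tuple[SlopeSeries, PlasticityResult]:
    """Slope series -> baseline -> plasticity magnitude for one pathway."""
    series = slope_series(sweeps, pathway=pathway)
    base = baseline_slope(series, n=n_baseline)
    result = plasticity_magnitude(
        series, base, endpoint_window=endpoint_window, n_baseline=n_baseline
    )
    return series, result
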