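"""Seeded generators for imaging stacks and electrophysiology sweeps.

Every generator carries its ground truth alongside the data so downstream
stages can be tested by parameter recovery without any external recordings:

* :func:`gen_intrinsic_stack` / :func:`gen_session` — periodic bar-sweep
  reflectance movies with a known per-pixel modulation amplitude per eye
  (fractional, order 1e-4) confined to a binocular zone, plus white noise;
* :func:`gen_sr_sweeps` — 1500 ms voltage-clamp sweeps with Poisson
  spontaneous events over the whole sweep and extra evoked events in a
  750-1150 ms window, difference-of-exponentials kinetics and Gaussian
  baseline noise;
* :func:`gen_stdp_sweeps` — current-clamp EPSP sweeps every 20 s whose
  initial rising phase is linear at a controlled slope, scaled by
  ``post_ratio`` after the pairing mark.

All randomness flows from one integer seed; sub-streams are derived
deterministically per stack/sweep so identical calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .imaging import DIRECTIONS, EYES, IntrinsicStack
from .quantal import SweepSet
from .stdp import EpspSweep

try:  # pragma: no cover - exercised implicitly
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _fill_stack(noise2d, cosvec, amp_flat, sigma):
        """In place: noise2d[t, p] = 1 + amp[p]*cos[t] + sigma*noise2d[t, p]."""
        T, P = noise2d.shape
        for t in range(T):
            ct = cosvec[t]
            for p in range(P):
                noise2d[t, p] = 1.0 + ct * amp_flat[p] + sigma * noise2d[t, p]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


# --------------------------------------------------------------------------
# imaging truth and stack generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingTruth:
    """Ground truth for one synthetic imaging session.

    ``amp_contra_map`` / ``amp_ipsi_map`` hold the true fractional modulation
    amplitude per pixel (order 1e-4), zero outside ``zone_mask``.
    ``hemo_phase`` maps drift direction (deg) to the response phase offset.
    """

    amp_contra_map: np.ndarray
    amp_ipsi_map: np.ndarray
    zone_mask: np.ndarray
    noise_sd: float
    hemo_phase: dict
    seed: int

    def __post_init__(self) -> None:
        for name in ("amp_contra_map", "amp_ipsi_map"):
            m = getattr(self, name)
            if m.shape != self.zone_mask.shape:
                raise ParameterError(f"{name} shape differs from zone_mask")
            if np.any(m < 0):
                raise ParameterError(f"{name} must be non-negative")
            if np.any(m[~self.zone_mask] != 0):
                raise ParameterError(f"{name} must vanish outside zone_mask")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        missing = set(DIRECTIONS) - {float(d) for d in self.hemo_phase}
        if missing:
            raise ParameterError(f"hemo_phase missing directions {missing}")

    @property
    def true_odi(self) -> float:
        """Mean over the zone of pixelwise (C-I)/(C+I) of the truth maps."""
        c = self.amp_contra_map[self.zone_mask]
        i = self.amp_ipsi_map[self.zone_mask]
        return float(((c - i) / (c + i)).mean())

    def amp_map(self, eye: str) -> np.ndarray:
        if eye == "contra":
            return self.amp_contra_map
        if eye == "ipsi":
            return self.amp_ipsi_map
        raise ParameterError(f"unknown eye {eye!r}")

    def swapped(self) -> "ImagingTruth":
        """Truth with the two eyes' amplitude maps exchanged."""
        return replace(
            self,
            amp_contra_map=self.amp_ipsi_map,
            amp_ipsi_map=self.amp_contra_map,
        )

    @classmethod
    def uniform_disk(
        cls,
        shape: tuple[int, int] = (64, 64),
        radius: float = 20.0,
        center: tuple[float, float] | None = None,
        amp_contra: float = 2.5e-4,
        amp_ipsi: float = 1.3e-4,
        noise_sd: float = 1e-3,
        phases: tuple[float, float] = (0.8, 2.1),
        seed: int = 0,
    ) -> "ImagingTruth":
        """Flat-top disk zone with uniform per-eye amplitudes."""
        if amp_contra < 0 or amp_ipsi < 0 or amp_contra + amp_ipsi <= 0:
            raise ParameterError("amplitudes must be non-negative, not both zero")
        h, w = shape
        cy, cx = center if center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
        yy, xx = np.mgrid[0:h, 0:w]
        zone = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        return cls(
            amp_contra_map=np.where(zone, amp_contra, 0.0),
            amp_ipsi_map=np.where(zone, amp_ipsi, 0.0),
            zone_mask=zone,
            noise_sd=noise_sd,
            hemo_phase={90.0: phases[0], 270.0: phases[1]},
            seed=seed,
        )

    @classmethod
    def from_odi(cls, odi: float, mean_amp: float = 1.9e-4, **kwargs) -> "ImagingTruth":
        """Uniform-disk truth whose pixelwise ODI equals ``odi`` everywhere."""
        if not -1.0 <= odi <= 1.0:
            raise ParameterError("odi must lie in [-1, 1]")
        return cls.uniform_disk(
            amp_contra=mean_amp * (1.0 + odi),
            amp_ipsi=mean_amp * (1.0 - odi),
            **kwargs,
        )


_EYE_CODE = {e: i for i, e in enumerate(EYES)}
_DIR_CODE = {d: i for i, d in enumerate(DIRECTIONS)}


def gen_intrinsic_stack(
    height: int,
    width: int,
    duration: float,
    frame_rate: float,
    stim_freq: float,
    eye: str,
    direction: float,
    truth: ImagingTruth,
    dtype=np.float64,
) -> IntrinsicStack:
    """Reflectance movie ``R(t) = R0 (1 + a(x,y) cos(2 pi f t + phi)) + eps``.

    ``R0`` is 1 per pixel (only the fractional change matters), ``a`` is the
    eye's truth amplitude map, ``phi`` the direction's hemodynamic phase and
    ``eps`` white Gaussian noise with sd ``truth.noise_sd``.
    """
    if duration <= 0 or frame_rate <= 0 or stim_freq <= 0:
        raise ParameterError("duration, frame_rate and stim_freq must be positive")
    if duration * stim_freq < 2:
        raise ParameterError("need at least 2 stimulus cycles per acquisition")
    if frame_rate <= 2 * stim_freq:
        raise ParameterError("frame_rate must exceed twice the stimulus frequency")
    if (height, width) != truth.zone_mask.shape:
        raise ParameterError(
            f"requested {height}x{width} but truth maps are "
            f"{truth.zone_mask.shape[0]}x{truth.zone_mask.shape[1]}"
        )
    direction = float(direction)
    T = int(round(duration * frame_rate))
    t = np.arange(T) / frame_rate
    phi = float(truth.hemo_phase[direction])
    cosv = np.cos(2.0 * np.pi * stim_freq * t + phi).astype(dtype)
    amp = truth.amp_map(eye).astype(dtype).ravel()

    if truth.noise_sd == 0:
        frames = (1.0 + cosv[:, None] * amp[None, :]).reshape(T, height, width)
    else:
        # Philox: counter-based, fastest of numpy's bit generators for the
        # ~150M draws a full session needs
        rng = np.random.Generator(
            np.random.Philox(
                np.random.SeedSequence(
                    [truth.seed, 101, _EYE_CODE[eye], _DIR_CODE[direction]]
                )
            )
        )
        buf = rng.standard_normal(T * height * width, dtype=dtype).reshape(T, -1)
        if _HAVE_NUMBA:
            _fill_stack(buf, cosv, amp, dtype(truth.noise_sd))
        else:
            buf *= dtype(truth.noise_sd)
            buf += 1.0
            buf += cosv[:, None] * amp[None, :]
        frames = buf.reshape(T, height, width)
    return IntrinsicStack(
        frames=frames,
        frame_rate=frame_rate,
        stim_freq=stim_freq,
        eye=eye,
        direction=direction,
    )


def gen_session(
    truth: ImagingTruth,
    duration: float = 300.0,
    frame_rate: float = 30.0,
    stim_freq: float = 0.12,
    dtype=np.float64,
) -> dict[tuple[str, float], IntrinsicStack]:
    """The four acquisitions of one session: {contra, ipsi} x {90, 270} deg.

    All stacks share geometry and timing; the two directions differ only in
    phase, the two eyes only in amplitude map.  The default 0.12 Hz bar-sweep
    frequency gives 36 integer cycles in 300 s (an exact DFT bin).
    """
    h, w = truth.zone_mask.shape
    return {
        (eye, d): gen_intrinsic_stack(
            h, w, duration, frame_rate, stim_freq, eye, d, truth, dtype=dtype
        )
        for eye in EYES
        for d in DIRECTIONS
    }


# --------------------------------------------------------------------------
# Sr2+ sweep generation
# --------------------------------------------------------------------------

EVOKED_WINDOW = (0.75, 1.15)  # s; matches the post analysis window
SWEEP_DURATION = 1.5  # s
STIM_ONSET = 0.7  # s
TEST_PULSE_WINDOW = (0.0, 0.1)  # s, excluded from analysis


@dataclass(frozen=True)
class EphysTruth:
    """Ground truth for one synthetic Sr2+ cell.

    ``evoked_rate`` is the rate of the *additional* evoked process inside
    the evoked window, on top of the spontaneous process that runs through
    the whole sweep.  ``event_log`` is filled in by :func:`gen_sr_sweeps`.
    """

    spont_rate: float = 1.0  # events/s over the whole sweep
    evoked_rate: float = 7.0  # extra events/s inside EVOKED_WINDOW
    spont_amp_mean: float = 12.0  # pA
    evoked_amp_mean: float = 18.0  # pA
    amp_cv: float = 0.2
    noise_rms: float = 2.0  # pA
    tau_rise_ms: float = 0.5  # kernel time constants; 10-90% rise ~1 ms
    tau_decay_ms: float = 6.0
    seed: int = 0
    event_log: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.spont_rate < 0 or self.evoked_rate < 0:
            raise ParameterError("rates must be >= 0")
        if self.spont_amp_mean <= 0 or self.evoked_amp_mean <= 0:
            raise ParameterError("amplitudes must be positive")
        if self.amp_cv < 0 or self.noise_rms < 0:
            raise ParameterError("amp_cv and noise_rms must be >= 0")
        if self.tau_rise_ms <= 0 or self.tau_decay_ms <= self.tau_rise_ms:
            raise ParameterError("need 0 < tau_rise < tau_decay")

    @property
    def true_corrected_amp(self) -> float:
        """The corrected evoked amplitude implied by the true rates/means."""
        pre_rate = self.spont_rate
        post_rate = self.spont_rate + self.evoked_rate
        post_amp = (
            self.spont_amp_mean * pre_rate + self.evoked_amp_mean * self.evoked_rate
        ) / post_rate
        return (post_amp * post_rate - self.spont_amp_mean * pre_rate) / (
            post_rate - pre_rate
        )


def event_kernel(
    sampling_rate: float, tau_rise_ms: float = 0.5, tau_decay_ms: float = 6.0
) -> np.ndarray:
    """Difference-of-exponentials inward unit kernel, sampled peak = -1."""
    tr = tau_rise_ms * 1e-3
    td = tau_decay_ms * 1e-3
    length = int(round(8 * td * sampling_rate))
    t = np.arange(length) / sampling_rate
    k = np.exp(-t / td) - np.exp(-t / tr)
    return -k / k.max()


def kernel_rise_time_ms(kernel: np.ndarray, sampling_rate: float) -> float:
    """10-90% rise time of an inward unit kernel, in ms."""
    depth = -kernel.min()
    i_peak = int(np.argmin(kernel))
    seg = -kernel[: i_peak + 1]
    t10 = np.interp(0.1 * depth, seg, np.arange(len(seg)))
    t90 = np.interp(0.9 * depth, seg, np.arange(len(seg)))
    return float((t90 - t10) / sampling_rate * 1e3)


def gen_sr_sweeps(
    n_sweeps: int,
    truth: EphysTruth,
    sampling_rate: float = 10_000.0,
    test_pulse_pa: float = -50.0,
) -> tuple[SweepSet, EphysTruth]:
    """Generate one cell's Sr2+ sweeps and its per-event ground-truth log.

    Each 1500 ms sweep holds a square test-pulse response in the documented
    (excluded) window, spontaneous events as a Poisson process over the whole
    sweep, extra evoked events inside 750-1150 ms, and white noise.
    """
    if n_sweeps < 1:
        raise ParameterError("n_sweeps must be >= 1")
    if sampling_rate < 5000:
        raise ParameterError("sampling_rate must be >= 5 kHz")
    if EVOKED_WINDOW[1] > SWEEP_DURATION:
        raise ParameterError("evoked window exceeds the sweep")
    rng = np.random.default_rng([truth.seed, 202])
    n_samples = int(round(SWEEP_DURATION * sampling_rate))
    kernel = event_kernel(sampling_rate, truth.tau_rise_ms, truth.tau_decay_ms)
    rise_ms = kernel_rise_time_ms(kernel, sampling_rate)
    klen = len(kernel)
    tp_lo = int(round(TEST_PULSE_WINDOW[0] * sampling_rate))
    tp_hi = int(round(TEST_PULSE_WINDOW[1] * sampling_rate))

    sweeps = np.zeros((n_sweeps, n_samples))
    log_rows = []
    for si in range(n_sweeps):
        trace = sweeps[si]
        trace[tp_lo:tp_hi] = test_pulse_pa
        n_sp = rng.poisson(truth.spont_rate * SWEEP_DURATION)
        t_sp = rng.uniform(0.0, SWEEP_DURATION, n_sp)
        n_ev = rng.poisson(truth.evoked_rate * (EVOKED_WINDOW[1] - EVOKED_WINDOW[0]))
        t_ev = rng.uniform(EVOKED_WINDOW[0], EVOKED_WINDOW[1], n_ev)
        for times, amp_mean, kind in (
            (t_sp, truth.spont_amp_mean, "spont"),
            (t_ev, truth.evoked_amp_mean, "evoked"),
        ):
            for t0 in np.sort(times):
                if truth.amp_cv > 0:
                    shape = 1.0 / truth.amp_cv**2
                    amp = rng.gamma(shape, amp_mean / shape)
                else:
                    amp = amp_mean
                i0 = int(round(t0 * sampling_rate))
                seg = kernel[: n_samples - i0]
                trace[i0 : i0 + len(seg)] += amp * seg
                log_rows.append((si, t0, amp, rise_ms, kind))
        if truth.noise_rms > 0:
            trace += rng.normal(0.0, truth.noise_rms, n_samples)

    log = pd.DataFrame(
        log_rows, columns=["sweep_index", "time", "amplitude", "rise_time_ms", "kind"]
    )
    sweep_set = SweepSet(
        sweeps=sweeps,
        sampling_rate=sampling_rate,
        stim_onset=STIM_ONSET,
        test_pulse_window=TEST_PULSE_WINDOW,
    )
    return sweep_set, replace(truth, event_log=log)


def detection_recall(
    event_log: pd.DataFrame,
    events: pd.DataFrame,
    min_amplitude: float = 0.0,
    exclude_windows: tuple = ((TEST_PULSE_WINDOW[0], TEST_PULSE_WINDOW[1] + 0.005),),
    match_tol: float = 0.005,
) -> float:
    """Fraction of true events recovered by a detection run.

    True events below ``min_amplitude`` or starting inside an excluded
    window (the test pulse is excluded from analysis by design) are dropped
    from the denominator; a true event counts as recovered when a detected
    event in the same sweep starts within ``match_tol`` seconds.
    """
    sel = event_log[event_log["amplitude"] >= min_amplitude]
    for lo, hi in exclude_windows:
        sel = sel[~((sel["time"] >= lo) & (sel["time"] < hi))]
    if len(sel) == 0:
        return float("nan")
    hits = 0
    for _, row in sel.iterrows():
        near = events[
            (events["sweep_index"] == row["sweep_index"])
            & ((events["time"] - row["time"]).abs() < match_tol)
        ]
        hits += len(near) > 0
    return hits / len(sel)


# --------------------------------------------------------------------------
# STDP sweep generation
# --------------------------------------------------------------------------

def gen_stdp_sweeps(
    baseline_slope: float,
    post_ratio: float,
    n_baseline: int = 30,
    n_post: int = 90,
    slope_noise_frac: float = 0.0,
    voltage_noise_mv: float = 0.0,
    sampling_rate: float = 10_000.0,
    seed: int = 0,
    sweep_interval: float = 20.0,
    stim_time: float = 0.1,
    latency_ms: float = 2.0,
    rise_ms: float = 3.0,
    decay_tau_ms: float = 25.0,
    rest_mv: float = -65.0,
    sweep_duration: float = 0.4,
) -> list[EpspSweep]:
    """EPSP sweeps every 20 s with a controlled, linear initial slope.

    Baseline sweeps (negative acquisition times) rise at ``baseline_slope``
    mV/ms; post-pairing sweeps at ``baseline_slope * post_ratio``.  The EPSP
    rises linearly for ``rise_ms`` after an onset ``latency_ms`` past the
    stimulus, then decays exponentially, so the first-2-ms regression
    recovers the programmed slope exactly in the noise-free case.
    """
    if baseline_slope <= 0:
        raise ParameterError("baseline_slope must be positive")
    if post_ratio <= 0:
        raise ParameterError("post_ratio must be positive")
    if n_baseline < 30:
        raise ParameterError("need at least 30 baseline sweeps")
    if n_post < 1:
        raise ParameterError("n_post must be >= 1")
    rng = np.random.default_rng([seed, 303])
    n_samples = int(round(sweep_duration * sampling_rate))
    t = np.arange(n_samples) / sampling_rate
    onset = stim_time + latency_ms * 1e-3
    rise = rise_ms * 1e-3
    tau = decay_tau_ms * 1e-3

    def make_sweep(slope_mv_per_ms: float, acq_time: float) -> EpspSweep:
        peak = slope_mv_per_ms * rise_ms
        v = np.full(n_samples, rest_mv)
        rising = (t >= onset) & (t < onset + rise)
        v[rising] += slope_mv_per_ms * (t[rising] - onset) * 1e3
        decaying = t >= onset + rise
        v[decaying] += peak * np.exp(-(t[decaying] - onset - rise) / tau)
        if voltage_noise_mv > 0:
            v = v + rng.normal(0.0, voltage_noise_mv, n_samples)
        return EpspSweep(
            voltage=v,
            sampling_rate=sampling_rate,
            stim_time=stim_time,
            acquisition_time=acq_time,
        )

    sweeps = []
    for i in range(n_baseline):
        s = baseline_slope
        if slope_noise_frac > 0:
            s = max(baseline_slope * (1.0 + rng.normal(0.0, slope_noise_frac)), 1e-6)
        sweeps.append(make_sweep(s, -sweep_interval * (n_baseline - i)))
    for i in range(n_post):
        s = baseline_slope * post_ratio
        if slope_noise_frac > 0:
            s = max(s * (1.0 + rng.normal(0.0, slope_noise_frac)), 1e-6)
        sweeps.append(make_sweep(s, sweep_interval * (i + 1)))
    return sweeps
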