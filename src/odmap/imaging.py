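"""Periodic-stimulus intrinsic-signal analysis and ocular dominance index.

The processing chain for one imaging session is:

1. per-stack Fourier extraction of the response magnitude at the stimulus
   frequency (:func:`fourier_response_map`),
2. averaging of the two drift-direction maps per eye
   (:func:`average_directions`),
3. 5x5 Gaussian smoothing (:func:`smooth_map`),
4. binocular ROI at 30% of the peak of the smoothed ipsilateral map
   (:func:`define_binocular_roi`),
5. per-eye ROI amplitudes and the mean pixelwise (C-I)/(C+I) index
   (:func:`roi_amplitude`, :func:`compute_odi`).

:func:`analyze_session` runs the chain on the four stacks of one session
(two eyes x two drift directions) and keeps every stage output.

Magnitudes are expressed as fractional reflectance change x 10^4 throughout,
so a pixel modulating with fractional amplitude 2.5e-4 maps to 2.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import (
    DegeneratePixelError,
    NoRoiError,
    ParameterError,
    ValidationError,
)

EYES = ("contra", "ipsi")
DIRECTIONS = (90.0, 270.0)

#: scale factor between fractional reflectance change and reported magnitude
MAGNITUDE_SCALE = 1e4


@dataclass(frozen=True)
class IntrinsicStack:
    """A reflectance movie for one (eye, drift direction) acquisition.

    ``frames`` is a (T, H, W) array of positive reflectance values in
    arbitrary units; only the fractional modulation matters downstream.
    """

    frames: np.ndarray
    frame_rate: float
    stim_freq: float
    eye: str
    direction: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ParameterError("frames must be a T x H x W array")
        if self.frame_rate <= 0 or self.stim_freq <= 0:
            raise ParameterError("frame_rate and stim_freq must be positive")
        if self.eye not in EYES:
            raise ParameterError(f"eye must be one of {EYES}, got {self.eye!r}")
        if float(self.direction) not in DIRECTIONS:
            raise ParameterError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if self.n_cycles < 2:
            raise ParameterError(
                f"stack spans {self.n_cycles:.2f} stimulus cycles; need >= 2"
            )

    @property
    def duration(self) -> float:
        return self.frames.shape[0] / self.frame_rate

    @property
    def n_cycles(self) -> float:
        return self.frames.shape[0] * self.stim_freq / self.frame_rate

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class ResponseMap:
    """Per-pixel response magnitude (x10^4) at the stimulus frequency."""

    magnitude: np.ndarray
    eye: str
    phase: np.ndarray | None = None
    smoothed: bool = False

    def __post_init__(self) -> None:
        if self.magnitude.ndim != 2:
            raise ParameterError("magnitude must be 2-D")
        if np.any(self.magnitude < 0):
            raise ParameterError("magnitude must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape


@dataclass(frozen=True)
class RoiMask:
    """Binocular region of interest from the smoothed ipsilateral map."""

    mask: np.ndarray
    threshold_fraction: float
    peak_value: float

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class OdiResult:
    """Per-eye ROI amplitudes, mean pixelwise ODI and its pixel histogram."""

    amp_contra: float
    amp_ipsi: float
    odi: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_pixels: int
    threshold_fraction: float = 0.3


@dataclass(frozen=True)
class SessionAnalysis:
    """All stage outputs of :func:`analyze_session` for one session."""

    raw_maps: Mapping[tuple[str, float], ResponseMap]
    eye_maps: Mapping[str, ResponseMap]
    smoothed_maps: Mapping[str, ResponseMap]
    roi: RoiMask
    odi_result: OdiResult
    params: dict = field(default_factory=dict)


def fourier_response_map(stack: IntrinsicStack) -> ResponseMap:
    """Extract the per-pixel response at the stimulus frequency.

    Per pixel the magnitude is ``2 |X_k*| / |X_0| * 1e4`` where ``X`` is the
    DFT of the pixel time series, ``X_0`` its zero-frequency component and
    ``k*`` the bin nearest ``stim_freq``.  A noise-free cosine of fractional
    amplitude ``a`` spanning an integer number of cycles therefore maps to
    exactly ``a * 1e4``.
    """
    T = stack.frames.shape[0]
    nyquist = stack.frame_rate / 2.0
    if stack.stim_freq >= nyquist:
        raise ParameterError(
            f"stim_freq {stack.stim_freq} Hz >= Nyquist {nyquist} Hz"
        )
    k_exact = stack.stim_freq * T / stack.frame_rate
    k = int(round(k_exact))
    k = min(max(k, 1), T // 2)
    if abs(k_exact - k) > 0.01:
        warnings.warn(
            f"stimulus frequency is {abs(k_exact - k):.3f} bins off the "
            f"nearest DFT bin; spectral leakage will bias the magnitude",
            stacklevel=2,
        )
    t = np.arange(T)
    ang = 2.0 * np.pi * k * t / T
    cosv = np.cos(ang)
    sinv = np.sin(ang)
    flat = stack.frames.reshape(T, -1)
    # X_k = sum_t x_t exp(-i ang); real/imag computed as two gemv calls so a
    # float32 stack is never copied to complex128.
    re = cosv.astype(flat.dtype) @ flat
    im = -(sinv.astype(flat.dtype) @ flat)
    x0 = flat.sum(axis=0, dtype=flat.dtype)
    mag = (2.0 * np.hypot(re, im) / np.abs(x0)) * MAGNITUDE_SCALE
    phase = np.arctan2(im, re)
    shape = stack.shape
    return ResponseMap(
        magnitude=np.asarray(mag, dtype=float).reshape(shape),
        phase=np.asarray(phase, dtype=float).reshape(shape),
        eye=stack.eye,
        smoothed=False,
    )


def average_directions(map_up: ResponseMap, map_down: ResponseMap) -> ResponseMap:
    """Pixelwise mean of the two opposite-drift-direction magnitude maps.

    Phase is dropped: hemodynamic delay gives each direction its own phase
    offset and only the magnitude is used downstream.
    """
    if map_up.eye != map_down.eye:
        raise ValidationError(
            f"direction maps from different eyes: {map_up.eye} vs {map_down.eye}"
        )
    if map_up.shape != map_down.shape:
        raise ValidationError(
            f"geometry mismatch: {map_up.shape} vs {map_down.shape}"
        )
    mean = 0.5 * (map_up.magnitude + map_down.magnitude)
    return ResponseMap(magnitude=mean, phase=None, eye=map_up.eye, smoothed=False)


def gaussian_kernel_5x5(sigma: float = 1.0) -> np.ndarray:
    """Normalized 5x5 Gaussian kernel (unit sum)."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    d = np.arange(-2.0, 3.0)
    g = np.exp(-(d**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def smooth_map(rmap: ResponseMap, sigma: float = 1.0) -> ResponseMap:
    """Convolve the magnitude map with a normalized 5x5 Gaussian kernel.

    Borders are handled by reflection, which preserves the map mean.
    """
    if rmap.shape[0] < 5 or rmap.shape[1] < 5:
        raise ParameterError(f"map {rmap.shape} smaller than the 5x5 kernel")
    kernel = gaussian_kernel_5x5(sigma)
    sm = ndimage.correlate(rmap.magnitude, kernel, mode="reflect")
    np.clip(sm, 0.0, None, out=sm)  # guard tiny negative round-off
    return ResponseMap(magnitude=sm, phase=None, eye=rmap.eye, smoothed=True)


def define_binocular_roi(
    smoothed_ipsi: ResponseMap,
    threshold_fraction: float = 0.3,
    connectivity: str = "peak",
) -> RoiMask:
    """Threshold the smoothed ipsilateral map at a fraction of its peak.

    Parameters
    ----------
    smoothed_ipsi:
        Smoothed ipsilateral-eye magnitude map.
    threshold_fraction:
        Pixels >= ``threshold_fraction * peak`` are ROI candidates.
    connectivity:
        ``"peak"`` keeps the 8-connected component containing the peak pixel
        (default; rejects disconnected supra-threshold noise blobs);
        ``"all"`` keeps every supra-threshold pixel.
    """
    if not smoothed_ipsi.smoothed:
        raise ValidationError("ROI must be defined on a smoothed map")
    if not 0 < threshold_fraction <= 1:
        raise ParameterError("threshold_fraction must be in (0, 1]")
    if connectivity not in ("peak", "all"):
        raise ParameterError("connectivity must be 'peak' or 'all'")
    mag = smoothed_ipsi.magnitude
    peak = float(mag.max())
    if peak <= 0:
        raise NoRoiError("all-zero smoothed map: no ROI can be defined")
    candidates = mag >= threshold_fraction * peak
    if connectivity == "peak":
        labels, _ = ndimage.label(candidates, structure=np.ones((3, 3), int))
        peak_idx = np.unravel_index(int(np.argmax(mag)), mag.shape)
        mask = labels == labels[peak_idx]
    else:
        mask = candidates
    return RoiMask(mask=mask, threshold_fraction=threshold_fraction, peak_value=peak)


def roi_amplitude(rmap: ResponseMap, roi: RoiMask) -> float:
    """Mean magnitude over the ROI pixels."""
    if rmap.shape != roi.mask.shape:
        raise ValidationError(
            f"geometry mismatch: map {rmap.shape} vs ROI {roi.mask.shape}"
        )
    if roi.n_pixels == 0:
        raise ValidationError("empty ROI mask")
    return float(rmap.magnitude[roi.mask].mean())


def compute_odi(
    contra: ResponseMap,
    ipsi: ResponseMap,
    roi: RoiMask,
    n_bins: int = 50,
) -> OdiResult:
    """Mean pixelwise (C-I)/(C+I) over the ROI, with its pixel histogram.

    The pixelwise definition is authoritative: the ODI is the mean of the
    per-pixel indices, not the index of the mean amplitudes.
    """
    if not (contra.smoothed and ipsi.smoothed):
        raise ValidationError("compute_odi expects smoothed maps")
    if contra.shape != ipsi.shape or contra.shape != roi.mask.shape:
        raise ValidationError("geometry mismatch between maps and ROI")
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    c = contra.magnitude[roi.mask]
    i = ipsi.magnitude[roi.mask]
    denom = c + i
    if np.any(denom <= 0):
        bad = np.argwhere(roi.mask)[denom <= 0]
        raise DegeneratePixelError(map(tuple, bad))
    odi_p = (c - i) / denom
    counts, edges = np.histogram(odi_p, bins=n_bins, range=(-1.0, 1.0))
    return OdiResult(
        amp_contra=roi_amplitude(contra, roi),
        amp_ipsi=roi_amplitude(ipsi, roi),
        odi=float(odi_p.mean()),
        bin_edges=edges,
        counts=counts,
        n_pixels=roi.n_pixels,
        threshold_fraction=roi.threshold_fraction,
    )


def analyze_session(
    stacks,
    threshold_fraction: float = 0.3,
    sigma: float = 1.0,
    n_bins: int = 50,
    connectivity: str = "peak",
) -> SessionAnalysis:
    """Run the full map -> average -> smooth -> ROI -> ODI chain.

    ``stacks`` is an iterable of the four :class:`IntrinsicStack` objects of
    one session (eyes {contra, ipsi} x directions {90, 270}).
    """
    by_key: dict[tuple[str, float], IntrinsicStack] = {}
    for st in stacks:
        by_key[(st.eye, float(st.direction))] = st
    expected = {(e, d) for e in EYES for d in DIRECTIONS}
    if set(by_key) != expected:
        raise ValidationError(
            f"incomplete session: have {sorted(by_key)}, need {sorted(expected)}"
        )
    shapes = {st.shape for st in by_key.values()}
    if len(shapes) != 1:
        raise ValidationError(f"stacks disagree on geometry: {shapes}")

    raw_maps = {key: fourier_response_map(st) for key, st in by_key.items()}
    eye_maps = {
        eye: average_directions(raw_maps[(eye, 90.0)], raw_maps[(eye, 270.0)])
        for eye in EYES
    }
    smoothed = {eye: smooth_map(m, sigma=sigma) for eye, m in eye_maps.items()}
    roi = define_binocular_roi(
        smoothed["ipsi"], threshold_fraction=threshold_fraction,
        connectivity=connectivity,
    )
    odi_result = compute_odi(smoothed["contra"], smoothed["ipsi"], roi, n_bins=n_bins)
    return SessionAnalysis(
        raw_maps=raw_maps,
        eye_maps=eye_maps,
        smoothed_maps=smoothed,
        roi=roi,
        odi_result=odi_result,
        params={
            "threshold_fraction": threshold_fraction,
            "sigma": sigma,
            "n_bins": n_bins,
            "connectivity": connectivity,
        },
    )


def swap_eyes(stack: IntrinsicStack) -> IntrinsicStack:
    """Return the same stack relabelled with the opposite eye."""
    other = "ipsi" if stack.eye == "contra" else "contra"
    return replace(stack, eye=other)
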