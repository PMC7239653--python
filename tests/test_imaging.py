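"""Unit and property tests for the intrinsic-imaging module."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sp_signal

from odmap import imaging, synthetic
from odmap.errors import (
    DegeneratePixelError,
    NoRoiError,
    ParameterError,
    ValidationError,
)
from odmap.imaging import (
    IntrinsicStack,
    ResponseMap,
    RoiMask,
    average_directions,
    compute_odi,
    define_binocular_roi,
    fourier_response_map,
    gaussian_kernel_5x5,
    roi_amplitude,
    smooth_map,
)

from .conftest import cosine_stack


def flat_map(values, eye="ipsi", smoothed=False):
    return ResponseMap(magnitude=np.asarray(values, float), eye=eye, smoothed=smoothed)


class TestFourierResponseMap:
    def test_constant_stack_zero_magnitude(self):
        st_ = cosine_stack(amp=0.0)
        m = fourier_response_map(st_)
        assert np.allclose(m.magnitude, 0.0, atol=1e-9)

    def test_cosine_closed_form(self):
        # 3e-4 fractional cosine on an exact bin -> 3.000 in x1e4 units
        st_ = cosine_stack(amp=3e-4, freq=0.12, duration=300.0, frame_rate=30.0)
        m = fourier_response_map(st_)
        assert np.all(np.abs(m.magnitude - 3.0) < 3.0 * 1e-6)

    def test_harmonic_rejection(self):
        # modulation at 2x stim_freq only -> ~0 at the stim_freq bin
        st_ = cosine_stack(amp=3e-4, freq=0.24, duration=300.0, frame_rate=30.0)
        st_ = IntrinsicStack(
            frames=st_.frames, frame_rate=30.0, stim_freq=0.12,
            eye="contra", direction=90.0,
        )
        m = fourier_response_map(st_)
        assert np.all(m.magnitude < 1e-6)

    def test_phase_recovered(self):
        st_ = cosine_stack(amp=3e-4, phase=1.1)
        m = fourier_response_map(st_)
        assert np.allclose(m.phase, 1.1, atol=1e-6)

    def test_off_bin_warns(self):
        st_ = cosine_stack(amp=3e-4, freq=0.125, duration=100.0, frame_rate=10.0)
        with pytest.warns(UserWarning, match="off the nearest DFT bin"):
            fourier_response_map(st_)

    def test_stim_freq_above_nyquist_rejected(self):
        with pytest.raises(ParameterError, match="Nyquist"):
            fourier_response_map(cosine_stack(amp=1e-4, freq=6.0, frame_rate=10.0))

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ParameterError, match="cycles"):
            cosine_stack(amp=1e-4, freq=0.12, duration=10.0)


class TestAverageDirections:
    def test_idempotent_on_identical_maps(self):
        m = flat_map(np.random.default_rng(0).uniform(0, 4, (8, 8)))
        out = average_directions(m, m)
        assert np.array_equal(out.magnitude, m.magnitude)

    def test_direct_arithmetic(self):
        out = average_directions(flat_map([[2.0]] * 5), flat_map([[4.0]] * 5))
        assert np.all(out.magnitude == 3.0)

    def test_commutative(self):
        rng = np.random.default_rng(1)
        a, b = flat_map(rng.uniform(0, 4, (6, 6))), flat_map(rng.uniform(0, 4, (6, 6)))
        assert np.array_equal(
            average_directions(a, b).magnitude, average_directions(b, a).magnitude
        )

    def test_eye_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="different eyes"):
            average_directions(flat_map([[1.0]], eye="contra"), flat_map([[1.0]]))

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="geometry"):
            average_directions(flat_map(np.ones((4, 4))), flat_map(np.ones((5, 5))))


class TestSmoothMap:
    def test_constant_preserved(self):
        out = smooth_map(flat_map(np.full((9, 9), 2.7)))
        assert np.allclose(out.magnitude, 2.7)
        assert out.smoothed

    def test_impulse_gives_kernel(self):
        m = np.zeros((11, 11))
        m[5, 5] = 1.0
        out = smooth_map(flat_map(m))
        kernel = gaussian_kernel_5x5(1.0)
        assert out.magnitude[5, 5] == pytest.approx(kernel[2, 2])
        assert out.magnitude.sum() == pytest.approx(1.0)
        assert np.allclose(out.magnitude[3:8, 3:8], kernel)

    def test_twice_equals_self_convolved_kernel(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0, 5, (16, 16))
        twice = smooth_map(smooth_map(flat_map(m))).magnitude
        # brute-force oracle: symmetric-pad convolution with k*k
        k = gaussian_kernel_5x5(1.0)
        kk = sp_signal.convolve2d(k, k)
        oracle = sp_signal.convolve2d(m, kk, mode="same")
        # interior pixels agree exactly; borders differ because reflection
        # applied twice is not reflection of the once-smoothed map
        assert np.allclose(twice[4:-4, 4:-4], oracle[4:-4, 4:-4], atol=1e-12)

    def test_mean_preserved_by_reflection(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 5, (12, 17))
        out = smooth_map(flat_map(m))
        assert out.magnitude.mean() == pytest.approx(m.mean(), rel=1e-12)

    def test_small_map_rejected(self):
        with pytest.raises(ParameterError, match="5x5"):
            smooth_map(flat_map(np.ones((3, 3))))


def brute_force_roi(mag, fraction):
    """Oracle: threshold + BFS 8-connected component containing the peak."""
    peak = np.unravel_index(np.argmax(mag), mag.shape)
    keep = mag >= fraction * mag.max()
    seen = np.zeros_like(keep)
    stack = [peak]
    seen[peak] = True
    while stack:
        y, x = stack.pop()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                ny, nx = y + dy, x + dx
                if (
                    0 <= ny < mag.shape[0]
                    and 0 <= nx < mag.shape[1]
                    and keep[ny, nx]
                    and not seen[ny, nx]
                ):
                    seen[ny, nx] = True
                    stack.append((ny, nx))
    return seen


class TestDefineBinocularRoi:
    def test_uniform_map_selects_everything(self):
        roi = define_binocular_roi(flat_map(np.full((8, 8), 1.5), smoothed=True))
        assert roi.mask.all()
        assert roi.n_pixels == 64

    def test_distant_dim_blob_excluded(self):
        m = np.zeros((20, 20))
        m[3:6, 3:6] = 10.0  # main blob, peak 10
        m[15:18, 15:18] = 2.5  # distant blob below 30% of 10
        roi = define_binocular_roi(flat_map(m, smoothed=True))
        assert roi.mask[4, 4]
        assert not roi.mask[16, 16]
        assert np.array_equal(roi.mask, brute_force_roi(m, 0.3))

    def test_connected_dim_region_excluded_by_threshold(self):
        m = np.zeros((10, 10))
        m[2, 2:8] = [10.0, 5.0, 4.0, 2.0, 8.0, 9.0]  # dip below 3.0 splits the row
        roi = define_binocular_roi(flat_map(m, smoothed=True))
        assert np.array_equal(roi.mask, brute_force_roi(m, 0.3))
        assert not roi.mask[2, 6]  # supra-threshold but disconnected from peak

    def test_all_mode_keeps_disconnected_pixels(self):
        m = np.zeros((10, 10))
        m[2, 2] = 10.0
        m[8, 8] = 9.0
        roi = define_binocular_roi(flat_map(m, smoothed=True), connectivity="all")
        assert roi.mask[8, 8]

    def test_threshold_one_keeps_only_peak_plateau(self):
        m = np.zeros((9, 9))
        m[4, 4] = m[4, 5] = 7.0
        roi = define_binocular_roi(
            flat_map(m, smoothed=True), threshold_fraction=1.0
        )
        assert roi.n_pixels == 2
        assert roi.mask[4, 4] and roi.mask[4, 5]

    def test_all_zero_rejected(self):
        with pytest.raises(NoRoiError):
            define_binocular_roi(flat_map(np.zeros((8, 8)), smoothed=True))

    def test_unsmoothed_rejected(self):
        with pytest.raises(ValidationError, match="smoothed"):
            define_binocular_roi(flat_map(np.ones((8, 8))))


class TestRoiAmplitude:
    def test_constant_map(self):
        roi = define_binocular_roi(flat_map(np.full((6, 6), 2.38), smoothed=True))
        assert roi_amplitude(flat_map(np.full((6, 6), 2.38)), roi) == pytest.approx(2.38)

    def test_two_pixel_mean(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[1, 1] = True
        roi = RoiMask(mask=mask, threshold_fraction=0.3, peak_value=3.0)
        m = np.zeros((4, 4))
        m[0, 0], m[1, 1] = 1.0, 3.0
        assert roi_amplitude(flat_map(m), roi) == pytest.approx(2.0)

    def test_invariant_to_outside_values(self):
        mask = np.zeros((4, 4), bool)
        mask[2, 2] = True
        roi = RoiMask(mask=mask, threshold_fraction=0.3, peak_value=1.0)
        m1 = np.zeros((4, 4))
        m1[2, 2] = 5.0
        m2 = m1 + 100 * ~mask
        assert roi_amplitude(flat_map(m1), roi) == roi_amplitude(flat_map(m2), roi)


def full_roi(shape):
    return RoiMask(mask=np.ones(shape, bool), threshold_fraction=0.3, peak_value=1.0)


class TestComputeOdi:
    def test_equal_eyes_give_zero(self):
        m = flat_map(np.full((6, 6), 2.0), smoothed=True)
        res = compute_odi(m, m, full_roi((6, 6)))
        assert res.odi == 0.0

    def test_uniform_three_to_one(self):
        c = flat_map(np.full((6, 6), 3.0), eye="contra", smoothed=True)
        i = flat_map(np.full((6, 6), 1.0), smoothed=True)
        assert compute_odi(c, i, full_roi((6, 6))).odi == pytest.approx(0.5)

    def test_pixelwise_definition_not_ratio_of_means(self):
        cm = np.array([[1.0, 3.0]])
        im_ = np.array([[1.0, 1.0]])
        res = compute_odi(
            flat_map(cm, eye="contra", smoothed=True),
            flat_map(im_, smoothed=True),
            full_roi((1, 2)),
        )
        assert res.odi == pytest.approx(0.25)  # (0 + 0.5)/2
        ratio_of_means = (cm.mean() - im_.mean()) / (cm.mean() + im_.mean())
        assert ratio_of_means == pytest.approx(1 / 3)
        assert res.odi != pytest.approx(ratio_of_means)

    def test_histogram_counts_sum_to_roi_size(self):
        rng = np.random.default_rng(5)
        c = flat_map(rng.uniform(0.1, 4, (9, 9)), eye="contra", smoothed=True)
        i = flat_map(rng.uniform(0.1, 4, (9, 9)), smoothed=True)
        res = compute_odi(c, i, full_roi((9, 9)), n_bins=17)
        assert res.counts.sum() == res.n_pixels == 81
        assert len(res.counts) == 17

    def test_degenerate_pixels_reported(self):
        c = flat_map(np.zeros((4, 4)), eye="contra", smoothed=True)
        i = flat_map(np.zeros((4, 4)), smoothed=True)
        with pytest.raises(DegeneratePixelError) as exc:
            compute_odi(c, i, full_roi((4, 4)))
        assert len(exc.value.pixels) == 16

    def test_eye_swap_negates_exactly(self):
        rng = np.random.default_rng(6)
        a = flat_map(rng.uniform(0.1, 4, (8, 8)), eye="contra", smoothed=True)
        b = flat_map(rng.uniform(0.1, 4, (8, 8)), smoothed=True)
        roi = full_roi((8, 8))
        d1 = compute_odi(a, b, roi).odi
        d2 = compute_odi(
            ResponseMap(b.magnitude, eye="contra", smoothed=True),
            ResponseMap(a.magnitude, eye="ipsi", smoothed=True),
            roi,
        ).odi
        assert d1 == -d2  # bitwise antisymmetry

    def test_scale_invariance_power_of_two_exact(self):
        rng = np.random.default_rng(7)
        c = rng.uniform(0.1, 4, (8, 8))
        i = rng.uniform(0.1, 4, (8, 8))
        roi = full_roi((8, 8))
        base = compute_odi(
            flat_map(c, eye="contra", smoothed=True), flat_map(i, smoothed=True), roi
        ).odi
        scaled = compute_odi(
            flat_map(4.0 * c, eye="contra", smoothed=True),
            flat_map(4.0 * i, smoothed=True),
            roi,
        ).odi
        assert base == scaled

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_odi_bounded(self, seed):
        rng = np.random.default_rng(seed)
        c = flat_map(rng.uniform(0, 4, (6, 6)) + 1e-9, eye="contra", smoothed=True)
        i = flat_map(rng.uniform(0, 4, (6, 6)) + 1e-9, smoothed=True)
        res = compute_odi(c, i, full_roi((6, 6)))
        assert -1.0 <= res.odi <= 1.0


class TestAnalyzeSession:
    def test_noise_free_truth_recovered(self, tiny_truth, tiny_session):
        res = imaging.analyze_session(tiny_session.values())
        expected = (2.5 - 1.3) / (2.5 + 1.3)
        assert tiny_truth.true_odi == pytest.approx(expected, abs=1e-12)
        assert res.odi_result.odi == pytest.approx(expected, abs=1e-3)

    def test_deterministic(self, tiny_session):
        r1 = imaging.analyze_session(tiny_session.values())
        r2 = imaging.analyze_session(tiny_session.values())
        assert r1.odi_result.odi == r2.odi_result.odi
        assert np.array_equal(r1.roi.mask, r2.roi.mask)

    def test_swapped_eyes_negate(self, tiny_truth):
        swapped = synthetic.gen_session(
            tiny_truth.swapped(), duration=25.0, frame_rate=6.0, stim_freq=0.12
        )
        base = synthetic.gen_session(
            tiny_truth, duration=25.0, frame_rate=6.0, stim_freq=0.12
        )
        o1 = imaging.analyze_session(base.values()).odi_result.odi
        o2 = imaging.analyze_session(swapped.values()).odi_result.odi
        assert o1 == pytest.approx(-o2, abs=1e-9)

    def test_incomplete_session_rejected(self, tiny_session):
        stacks = list(tiny_session.values())[:3]
        with pytest.raises(ValidationError, match="incomplete"):
            imaging.analyze_session(stacks)

    def test_roi_fraction_propagates(self, tiny_session):
        res = imaging.analyze_session(tiny_session.values(), threshold_fraction=0.5)
        assert res.odi_result.threshold_fraction == 0.5
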