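"""Frame correction, median stacking, and image-quality metrics."""

import math

import numpy as np
import pytest

from protonrad import (
    AcquisitionParams,
    FrameStack,
    Radiograph,
    RoiSpec,
    acquisition_time,
    compute_cnr,
    compute_snr,
    correct_frames,
    detectability_vs_frames,
    edge_fwhm,
    imaging_dose,
    line_pair_resolution,
    stack_median,
)
from protonrad.radiography import NoEdgeEnhancementError


def _stack(arrays, **kw):
    return FrameStack(np.array(arrays, dtype=float), **kw)


class TestCorrectFrames:
    def test_constant_hand_arithmetic(self):
        # raw 100, mean(dark) 10, mean(beam incl dark) 40 -> I_beam 30 -> 60
        raw = _stack([np.full((4, 4), 100.0)])
        dark = _stack([np.full((4, 4), 10.0)], role="dark")
        beam = _stack([np.full((4, 4), 40.0)], role="beam")
        out = correct_frames(raw, dark, beam)
        assert np.allclose(out.frames, 60.0)

    def test_zero_backgrounds_identity(self):
        raw = _stack([np.arange(16.0).reshape(4, 4)])
        zeros = _stack([np.zeros((4, 4))], role="dark")
        out = correct_frames(raw, zeros, _stack([np.zeros((4, 4))], role="beam"))
        assert np.array_equal(out.frames, raw.frames)

    def test_exact_cancellation_of_rendered_model(self):
        # frames built as gain*T + dark + beam-only background cancel to gain*(T-1)
        rng = np.random.default_rng(5)
        gain, t = 1000.0, rng.uniform(0.8, 1.0, (8, 8))
        dark_pat = rng.uniform(0, 20, (8, 8))
        beam_pat = np.full((8, 8), gain)
        raw = _stack([gain * t + dark_pat])
        dark = _stack([dark_pat], role="dark")
        beam = _stack([beam_pat + dark_pat], role="beam")
        out = correct_frames(raw, dark, beam)
        assert np.allclose(out.frames[0], gain * (t - 1.0), atol=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0, 100, (3, 6, 6))
        zeros = _stack([np.zeros((6, 6))], role="dark")
        beam = _stack([np.zeros((6, 6))], role="beam")
        once = correct_frames(_stack(raw), zeros, beam).frames
        scaled = correct_frames(_stack(3.0 * raw), zeros, beam).frames
        assert np.allclose(scaled, 3.0 * once)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            correct_frames(
                _stack([np.zeros((4, 4))]),
                _stack([np.zeros((5, 4))], role="dark"),
                _stack([np.zeros((4, 4))], role="beam"),
            )


class TestStackMedian:
    def test_single_frame_identity(self):
        frame = np.arange(9.0).reshape(3, 3)
        assert np.array_equal(stack_median(_stack([frame])).image, frame)

    def test_impulse_rejected(self):
        frames = np.full((5, 3, 3), 7.0)
        frames[2, 1, 1] = 65535.0
        assert np.allclose(stack_median(_stack(frames)).image, 7.0)

    def test_even_count_convention(self):
        frames = np.array([[[1.0]], [[2.0]], [[3.0]], [[4.0]]])
        assert stack_median(_stack(frames)).image[0, 0] == 2.5

    @pytest.mark.parametrize("n", [3, 5, 9])
    def test_tolerates_floor_half_impulses(self, n):
        rng = np.random.default_rng(n)
        base = rng.uniform(10, 100, (12, 12))
        frames = np.repeat(base[None], n, axis=0)
        clean = stack_median(_stack(frames)).image
        k = (n - 1) // 2
        corrupted = frames.copy()
        for r in range(12):
            for c in range(12):
                which = rng.choice(n, size=k, replace=False)
                corrupted[which, r, c] = rng.choice([0.0, 65535.0], size=k)
        assert np.array_equal(stack_median(_stack(corrupted)).image, clean)

    def test_provenance(self):
        radio = stack_median(_stack(np.zeros((21, 2, 2)), frame_rate_hz=8.4))
        assert radio.n_frames == 21
        assert radio.acquisition_time_s == pytest.approx(2.5)


class TestSnrCnr:
    def test_snr_hand_values(self):
        img = np.zeros((2, 2))
        img[0] = [1.0, 3.0]
        radio = Radiograph(img, 0.05)
        assert compute_snr(radio, RoiSpec(0, 1, 0, 2)) == pytest.approx(2.0)
        img2 = np.array([[0.0, 0.0, 4.0, 4.0]])
        assert compute_snr(Radiograph(img2, 0.05), RoiSpec(0, 1, 0, 4)) == pytest.approx(1.0)

    def test_snr_constant_roi_is_infinite(self, flat_radiograph):
        assert math.isinf(compute_snr(flat_radiograph, RoiSpec(0, 5, 0, 5)))

    def test_cnr_hand_value_and_antisymmetry(self):
        pattern = 10.0 * np.tile([1.0, -1.0], (10, 5))  # balanced: sd exactly 10
        img = np.zeros((10, 20))
        img[:, :10] = 120.0 + pattern
        img[:, 10:] = 100.0 + pattern
        radio = Radiograph(img, 0.05)
        a, b = RoiSpec(0, 10, 0, 10), RoiSpec(0, 10, 10, 20)
        assert compute_cnr(radio, a, b) == pytest.approx(2.0)
        # equal noise in both regions: swapping a and b flips the sign
        assert compute_cnr(radio, b, a) == pytest.approx(-2.0)

    def test_cnr_zero_for_identical_statistics(self):
        img = np.tile(np.array([90.0, 110.0]), (10, 10))
        radio = Radiograph(img, 0.05)
        assert compute_cnr(radio, RoiSpec(0, 10, 0, 10), RoiSpec(0, 10, 10, 20)) == 0.0

    def test_cnr_invariant_snr_shifts_under_offset(self):
        rng = np.random.default_rng(7)
        img = rng.normal(100.0, 5.0, (20, 40))
        img[:, :20] += 30.0
        radio = Radiograph(img, 0.05)
        a, b = RoiSpec(0, 20, 0, 20), RoiSpec(0, 20, 20, 40)
        cnr0 = compute_cnr(radio, a, b)
        snr0 = compute_snr(radio, b)
        shifted = Radiograph(img + 50.0, 0.05)
        assert compute_cnr(shifted, a, b) == pytest.approx(cnr0)
        sigma = img[:, 20:].std()
        assert compute_snr(shifted, b) == pytest.approx(snr0 + 50.0 / sigma)

    def test_overlapping_rois_rejected(self, flat_radiograph):
        with pytest.raises(ValueError, match="disjoint"):
            compute_cnr(flat_radiograph, RoiSpec(0, 10, 0, 10), RoiSpec(5, 15, 5, 15))


class TestEdgeFwhm:
    @staticmethod
    def _gaussian_profile_image(sigma_px, amplitude=50.0, plateau=100.0, width=200):
        x = np.arange(width, dtype=float)
        profile = plateau + amplitude * np.exp(-((x - width / 2) ** 2) / (2 * sigma_px**2))
        return Radiograph(np.tile(profile, (50, 1)), pixel_pitch_mm=0.05)

    @pytest.mark.parametrize("sigma_px", [2.0, 3.5, 5.0, 7.5, 10.0])
    def test_recovers_gaussian_fwhm(self, sigma_px):
        radio = self._gaussian_profile_image(sigma_px)
        fwhm = edge_fwhm(radio, RoiSpec(0, 50, 0, 200), edge_axis=0)
        expected = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma_px * 0.05
        assert fwhm == pytest.approx(expected, rel=0.02)

    def test_known_sigma_mm(self):
        # sigma 0.2 mm -> FWHM 0.471 mm at 0.05 mm pitch
        radio = self._gaussian_profile_image(0.2 / 0.05)
        fwhm = edge_fwhm(radio, RoiSpec(0, 50, 0, 200), edge_axis=0)
        assert fwhm == pytest.approx(0.471, rel=0.02)

    def test_sharp_edge_raises(self):
        img = np.zeros((50, 100))
        img[:, 50:] = 100.0
        with pytest.raises(NoEdgeEnhancementError):
            edge_fwhm(Radiograph(img, 0.05), RoiSpec(0, 50, 0, 100), edge_axis=0)


def _square_wave(freq_lp_mm, pitch_mm, width_px, blur_sigma_px=0.0):
    from scipy.ndimage import gaussian_filter1d

    x = np.arange(width_px) * pitch_mm
    bar = ((x * freq_lp_mm * 2).astype(int) % 2 == 0).astype(float)
    profile = 100.0 + 50.0 * bar
    if blur_sigma_px > 0:
        profile = gaussian_filter1d(profile, blur_sigma_px)
    return np.tile(profile, (40, 1))


class TestLinePairResolution:
    FREQS = (0.6, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)

    def _grid_image(self, blur_px=0.0, pitch=0.05, noise=None):
        group_w = 120
        img = np.hstack([_square_wave(f, pitch, group_w, blur_px) for f in self.FREQS])
        img = np.hstack([img, np.full((40, group_w), 125.0)])
        if noise is not None:
            img = img + noise
        spec = [
            (f, RoiSpec(0, 40, i * group_w + 10, (i + 1) * group_w - 10))
            for i, f in enumerate(self.FREQS)
        ]
        bg = RoiSpec(0, 40, len(self.FREQS) * group_w + 10, len(self.FREQS) * group_w + 110)
        return Radiograph(img, pitch), spec, bg

    def test_unblurred_resolves_highest_group(self):
        radio, spec, bg = self._grid_image()
        freq, warn = line_pair_resolution(radio, spec, bg)
        assert freq == 6.0 and not warn

    def test_blur_kills_high_frequencies(self):
        # blur sigma = half the 3 lp/mm bar width -> 3 lp/mm and above unresolved
        bar_px_3 = 1.0 / (2 * 3.0) / 0.05
        radio, spec, bg = self._grid_image(blur_px=bar_px_3 / 2 * 2.0)
        freq, _ = line_pair_resolution(radio, spec, bg)
        assert 0 < freq < 3.0

    def test_monotone_in_blur(self):
        resolved = []
        for blur in (0.0, 1.0, 2.5, 5.0, 9.0):
            radio, spec, bg = self._grid_image(blur_px=blur)
            resolved.append(line_pair_resolution(radio, spec, bg)[0])
        assert all(a >= b for a, b in zip(resolved, resolved[1:]))

    def test_pure_noise_returns_zero_with_warning(self):
        rng = np.random.default_rng(3)
        radio, spec, bg = self._grid_image()
        noisy = Radiograph(rng.normal(100, 30, radio.image.shape), 0.05)
        freq, warn = line_pair_resolution(noisy, spec, bg)
        assert freq == 0.0 and warn


class TestTimeAndDose:
    def test_paper_acquisition_times(self):
        assert round(acquisition_time(30, 8.4), 1) == 3.6
        assert acquisition_time(84, 8.4) == pytest.approx(10.0)

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            acquisition_time(0, 8.4)

    def test_dose_calibrations(self):
        assert imaging_dose(84, 1.98, 8.4) == pytest.approx(19.8)
        # 8 s-equivalent exposure at the mouse-position calibration
        assert imaging_dose(80, 2.875, 10.0) == pytest.approx(23.0)
        assert imaging_dose(10, 0.0, 8.4) == 0.0

    def test_proportionality_in_n(self):
        t1, d1 = acquisition_time(7, 8.4), imaging_dose(7, 1.98, 8.4)
        assert acquisition_time(21, 8.4) == pytest.approx(3 * t1)
        assert imaging_dose(21, 1.98, 8.4) == pytest.approx(3 * d1)


class TestDetectability:
    @staticmethod
    def _poisson_hole_stack(n_frames=64, seed=0):
        rng = np.random.default_rng(seed)
        expected = np.full((40, 40), 1000.0)
        expected[15:25, 15:25] = 1080.0  # a faint hole
        frames = rng.poisson(np.repeat(expected[None], n_frames, 0)).astype(float)
        return FrameStack(frames, 0.05, 8.4)

    def test_cnr_grows_like_sqrt_n(self):
        stack = self._poisson_hole_stack()
        rois = [(0.5, RoiSpec(16, 24, 16, 24), RoiSpec(2, 12, 2, 12))]
        table = detectability_vs_frames(stack, rois, 1.98, n_values=[16, 64])
        ratio = table.cnr.iloc[1] / table.cnr.iloc[0]
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_noiseless_constant_from_first_frame(self):
        expected = np.full((30, 30), 1000.0)
        expected[10:20, 10:20] = 1200.0
        frames = np.repeat(expected[None], 6, 0)
        stack = FrameStack(frames, 0.05, 8.4)
        rois = [(0.5, RoiSpec(11, 19, 11, 19), RoiSpec(0, 8, 0, 8))]
        table = detectability_vs_frames(stack, rois, 1.98)
        assert (table.smallest_resolved_feature_mm == 0.5).all()
        assert list(table.n_frames) == sorted(table.n_frames)
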