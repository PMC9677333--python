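"""Synthetic generators: phantoms, rendering, mouse pair, volumes, nuclei."""

import numpy as np
import pytest

from protonrad import (
    AcquisitionParams,
    FrameStack,
    Radiograph,
    RoiSpec,
    correct_frames,
    edge_fwhm,
    stack_median,
)
from protonrad.beam import DoseMap2D
from protonrad.nuclei import NucleiParams, make_nuclei_pair
from protonrad.phantoms import (
    EDGE_SIGMA_MM,
    GroundTruth,
    make_collimator_radiograph,
    make_edge_phantom,
    make_hole_grid_phantom,
    make_label_volume,
    make_lead_grid_phantom,
    make_mouse_pair,
    make_qa_film,
    render_frames,
    transmission_map,
    apply_similarity,
)


class TestPhantomSpecs:
    def test_hole_grid_smallest_aperture(self):
        spec = make_hole_grid_phantom()
        assert spec.meta["smallest_hole_mm"] == 0.3
        # holes are punched air: transmission higher at hole than plate
        trans = transmission_map(spec, 200)
        hole = spec.meta["holes"][0]
        r, c = (int(round(v)) for v in hole["center_px"])
        assert trans[r, c] > trans[r + 30, c]

    def test_hole_count_matches_layout(self):
        spec = make_hole_grid_phantom()
        n_disks = sum(1 for p in spec.primitives if p["kind"] == "disk")
        assert n_disks == spec.meta["n_holes"] == len(spec.meta["holes"])

    def test_lead_grid_frequency_span(self):
        spec = make_lead_grid_phantom()
        freqs = [g["freq_lp_per_mm"] for g in spec.meta["groups"]]
        assert min(freqs) == 0.6 and max(freqs) == 6.0

    def test_bar_width_is_half_period(self):
        # 2 lp/mm -> bar width 0.25 mm -> 5 px at 0.05 mm pitch
        spec = make_lead_grid_phantom()
        thick = spec.thickness_map()
        group = next(g for g in spec.meta["groups"] if g["freq_lp_per_mm"] == 2.0)
        r0, r1, c0, c1 = group["region"]
        row = thick[(r0 + r1) // 2, c0:c1]
        transitions = np.flatnonzero(np.abs(np.diff(row)) > row.max() * 0.4)
        widths = np.diff(transitions)
        assert np.median(widths) == pytest.approx(0.25 / 0.05, abs=1)


class TestTransmissionMap:
    def test_uniform_phantom_is_flat_unity(self):
        spec = make_edge_phantom()
        spec.primitives = [
            {"kind": "rectangle", "region": (-9, 249, -9, 329), "rsp": 1.0, "thickness_mm": 5.0}
        ]
        trans = transmission_map(spec, 200)
        assert np.allclose(trans, 1.0, atol=1e-6)

    def test_mean_fluence_conserved(self):
        for maker in (make_edge_phantom, make_hole_grid_phantom, make_lead_grid_phantom):
            trans = transmission_map(maker(), 200)
            assert abs(trans.mean() - 1.0) < 1e-3

    def test_edge_band_redistribution_integrates_to_zero(self):
        spec = make_edge_phantom()
        trans = transmission_map(spec, 200)
        edge = spec.meta["edge_col"]
        band = trans[60:180, edge - 40 : edge + 40]
        # valley inside and peak outside cancel relative to the far-field levels
        inside_base = np.median(band[:, :5])
        outside_base = np.median(band[:, -5:])
        total = (
            (band[:, :40] - inside_base).sum() + (band[:, 40:] - outside_base).sum()
        ) / band.size
        assert abs(total) < 2e-3

    def test_peak_wider_at_lower_energy(self):
        spec = make_edge_phantom()
        fwhms = {}
        for energy in (150, 200):
            radio = Radiograph(transmission_map(spec, energy), 0.05)
            fwhms[energy] = edge_fwhm(radio, RoiSpec(20, 220, 60, 260), edge_axis=0)
        assert fwhms[150] > fwhms[200]
        assert fwhms[150] - fwhms[200] == pytest.approx(0.08, abs=0.02)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            transmission_map(make_edge_phantom(), 42)


class TestRenderFrames:
    def test_same_seed_bit_identical(self):
        spec = make_edge_phantom((60, 80))
        trans = transmission_map(spec, 200)
        acq = AcquisitionParams(n_frames=4, poisson_noise=True, salt_pepper_fraction=0.01, seed=9)
        a = render_frames(trans, acq)
        b = render_frames(trans, acq)
        for x, y in zip(a[:3], b[:3]):
            assert np.array_equal(x.frames, y.frames)

    def test_seed_required_for_stochastic_render(self):
        with pytest.raises(ValueError, match="seed"):
            AcquisitionParams(poisson_noise=True, seed=None)

    def test_noiseless_roundtrip_recovers_signal(self):
        spec = make_edge_phantom((60, 80))
        trans = transmission_map(spec, 200)
        acq = AcquisitionParams(n_frames=3, poisson_noise=False, seed=None, gain=5000.0)
        raw, dark, beam, _ = render_frames(trans, acq)
        assert np.array_equal(raw.frames[0], raw.frames[1])
        corrected = stack_median(correct_frames(raw, dark, beam))
        from protonrad.phantoms import _beam_profile

        expected = acq.gain * _beam_profile(trans.shape, acq.beam_sigma_frac) * (trans - 1.0)
        assert np.allclose(corrected.image, expected, atol=1e-6)

    def test_poisson_scaling(self):
        trans = np.ones((24, 24))
        acq = AcquisitionParams(n_frames=100, poisson_noise=True, seed=4, gain=1.0e4)
        raw, _, _, _ = render_frames(trans, acq)
        centre = raw.frames[:, 12, 12]
        rel_std = centre.std() / centre.mean()
        assert rel_std == pytest.approx(1.0 / np.sqrt(centre.mean()), rel=0.10)


class TestCollimator:
    def test_disk_radius_and_area(self, collimator_noiseless):
        stack, gt = collimator_noiseless
        radio = stack_median(stack)
        # 3 mm aperture at 0.05 mm pitch -> radius 30 px
        assert gt.truth["radius_px"] == pytest.approx(30.0)
        bright = radio.image > (radio.image.min() + radio.image.max()) / 2
        assert bright.sum() == pytest.approx(np.pi * 30.0**2, rel=0.02)

    def test_truth_center_recorded(self, collimator_noiseless):
        _, gt = collimator_noiseless
        assert gt.truth["center_px"] == [120.0, 132.5]


class TestMousePair:
    def test_five_landmarks_consistent_with_transform(self, mouse_pair):
        truth = mouse_pair["ground_truth"].truth
        plan_lm = np.asarray(truth["plan_landmarks"])
        radio_lm = np.asarray(truth["radio_landmarks"])
        assert plan_lm.shape == (5, 2)
        mapped = apply_similarity(
            plan_lm, truth["scale"], truth["rotation_deg"], truth["translation_px"]
        )
        assert np.allclose(mapped, radio_lm, atol=1e-12)

    def test_identity_noiseless_radiograph_matches_plan(self):
        acq = AcquisitionParams(n_frames=2, poisson_noise=False, seed=None, gain=1000.0)
        data = make_mouse_pair(seed=0, true_transform=(1.0, 0.0, (0.0, 0.0)), acq=acq)
        radio = stack_median(
            correct_frames(data["radiograph_frames"], data["dark_frames"], data["beam_frames"])
        )
        plan = data["plan"]
        # corrected image is an affine (gain/offset) rendering of the plan
        corr = np.corrcoef(radio.image.ravel(), plan.ravel())[0, 1]
        assert corr > 0.999

    def test_transform_bounds_enforced(self):
        with pytest.raises(ValueError):
            make_mouse_pair(seed=0, true_transform=(2.5, 0.0, (0.0, 0.0)))
        with pytest.raises(ValueError):
            make_mouse_pair(seed=0, true_transform=(1.0, 45.0, (0.0, 0.0)))


class TestLabelVolume:
    def test_exactly_three_labels_and_nesting(self):
        labels, intensity, _ = make_label_volume((32, 32, 32), seed=1)
        assert set(np.unique(labels)) == {0, 1, 2}
        assert labels.shape == intensity.shape
        # hippocampus strictly inside brain: every 2-voxel has label >= 1 around it
        from scipy import ndimage

        hip = labels == 2
        grown = ndimage.binary_dilation(hip)
        assert (labels[grown] >= 1).all()

    def test_minimum_sagittal_planes(self):
        with pytest.raises(ValueError, match="sagittal"):
            make_label_volume((20, 64, 64))


class TestGroundTruthRoundTrip:
    def test_serialization_regenerates_identically(self, tmp_path):
        import json

        film, gt = make_qa_film(seed=12)
        path = tmp_path / "gt.json"
        path.write_text(json.dumps(gt.to_dict()))
        restored = GroundTruth.from_dict(json.loads(path.read_text()))
        assert restored.seed == gt.seed
        params = dict(restored.params)
        blank = params.pop("blank")
        film2, _ = make_qa_film(
            shape_px=tuple(params.pop("shape_px")),
            spot_center_px=tuple(params.pop("spot_center_px")),
            shadow_center_px=None if params["shadow_center_px"] is None else tuple(params.pop("shadow_center_px")),
            seed=restored.seed,
            blank=blank,
            **{k: v for k, v in params.items() if k != "shadow_center_px"},
        )
        assert np.array_equal(film, film2)


def _flat_dose(value, shape=(16, 16), px=0.1):
    return DoseMap2D(np.full(shape, float(value)), px)


class TestNuclei:
    def test_zero_dose_zero_background_no_damage(self):
        params = NucleiParams(shape_px=(128, 128), n_nuclei=40, p_bg=0.0)
        out = make_nuclei_pair(_flat_dose(0.0), params, seed=3)
        assert out["damaged"].sum() == 0
        assert out["tile_n_damage"].sum() == 0

    def test_saturating_dose_damages_all(self):
        params = NucleiParams(shape_px=(128, 128), n_nuclei=40, p_max=1.0, d50_gy=0.001)
        out = make_nuclei_pair(_flat_dose(1000.0), params, seed=3)
        assert out["damaged"].all()

    def test_truth_counts_match_placed(self):
        params = NucleiParams(shape_px=(256, 256), n_nuclei=120)
        out = make_nuclei_pair(_flat_dose(2.0), params, seed=5, tile_px=64)
        assert out["tile_n_dapi"].sum() == 120 == len(out["centers"])
        assert out["tile_n_damage"].sum() == out["damaged"].sum()

    def test_min_distance_respected(self):
        params = NucleiParams(shape_px=(256, 256), n_nuclei=150, min_distance_px=9.0)
        out = make_nuclei_pair(_flat_dose(1.0), params, seed=8)
        from scipy.spatial.distance import pdist

        assert pdist(out["centers"]).min() >= 9.0

    def test_impossible_density_raises(self):
        params = NucleiParams(
            shape_px=(64, 64), n_nuclei=500, min_distance_px=10.0, max_placement_tries=5
        )
        with pytest.raises(RuntimeError, match="placement"):
            make_nuclei_pair(_flat_dose(1.0), params, seed=1)
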