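"""Segmentation, per-nucleus metrics, IF registration and line profiles."""

import numpy as np
import pytest
from skimage.transform import resize

from chromaflim.decay_fit import LifetimeMap
from chromaflim.nuclei_if import (
    line_profile,
    nucleus_stats,
    records_to_frame,
    register_if_to_flim,
    segment_nuclei,
    suggest_profile_line,
)
from chromaflim.synthgen import SimConfig, default_axis, make_phantom, simulate_if_image


def lifetime_map_from(tau, mask, intensity) -> LifetimeMap:
    nanplane = np.full(tau.shape, np.nan)
    return LifetimeMap(
        tau=np.asarray(tau, dtype=np.float64),
        amplitude=nanplane.copy(),
        offset=nanplane.copy(),
        chi2=np.where(mask, 1.0, np.nan),
        intensity=np.asarray(intensity, dtype=np.float64),
        mask=np.asarray(mask, dtype=bool),
        axis=default_axis(64),
    )


@pytest.fixture
def three_nuclei_phantom():
    cfg = SimConfig(
        image_size=128, n_nuclei=3, nucleus_radius=18.0, n_foci=0,
        photons_per_pixel=1000.0, axis=default_axis(64), seed=5,
    )
    return make_phantom(cfg)


class TestSegmentNuclei:
    def test_three_discs_give_three_labels(self, three_nuclei_phantom):
        rng = np.random.default_rng(0)
        img = three_nuclei_phantom.brightness_map + rng.normal(0, 50, (128, 128))
        labels = segment_nuclei(img, min_area=100)
        assert labels.max() == 3

    def test_blank_image_warns_and_returns_no_labels(self):
        with pytest.warns(UserWarning, match="no nuclei"):
            labels = segment_nuclei(np.zeros((32, 32)))
        assert labels.max() == 0

    def test_disc_area_within_ten_percent(self, three_nuclei_phantom):
        rng = np.random.default_rng(1)
        img = three_nuclei_phantom.brightness_map + rng.normal(0, 50, (128, 128))
        labels = segment_nuclei(img, min_area=100)
        for lab in (1, 2, 3):
            assert (labels == lab).sum() == pytest.approx(np.pi * 18.0**2, rel=0.10)

    def test_determinism(self, three_nuclei_phantom):
        rng = np.random.default_rng(2)
        img = three_nuclei_phantom.brightness_map + rng.normal(0, 50, (128, 128))
        np.testing.assert_array_equal(segment_nuclei(img), segment_nuclei(img))


class TestNucleusStats:
    def test_constant_tau_nucleus_mean_exact(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[4:12, 4:12] = 1
        tau = np.where(labels == 1, 2500.0, np.nan)
        lm = lifetime_map_from(tau, labels == 1, np.where(labels == 1, 800.0, 0.0))
        (rec,) = nucleus_stats(labels, lm)
        assert rec.mean_tau == 2500.0
        assert rec.area == 64

    def test_two_state_nucleus_mean_is_arithmetic_mean(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[2:6, 2:6] = 1
        tau = np.full((8, 8), np.nan)
        tau[2:6, 2:4] = 2000.0
        tau[2:6, 4:6] = 2600.0
        lm = lifetime_map_from(tau, np.isfinite(tau), np.ones((8, 8)))
        (rec,) = nucleus_stats(labels, lm)
        assert rec.mean_tau == pytest.approx(2300.0)

    def test_shrunken_nucleus_area_ratio(self):
        # compaction readout: radius 20 -> 16 shrinks area by (16/20)^2
        cfg_big = SimConfig(image_size=64, nucleus_radius=20.0, n_foci=0, axis=default_axis(64), seed=1)
        cfg_small = SimConfig(image_size=64, nucleus_radius=16.0, n_foci=0, axis=default_axis(64), seed=1)
        big = (make_phantom(cfg_big).state_map > 0).sum()
        small = (make_phantom(cfg_small).state_map > 0).sum()
        assert small / big == pytest.approx(0.64, rel=0.10)

    def test_mean_tau_invariant_to_unmasked_pixels_and_relabeling(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[1:5, 1:5] = 2
        labels[6:9, 6:9] = 1
        tau = np.full((10, 10), np.nan)
        tau[1:5, 1:5] = 2400.0
        tau[6:9, 6:9] = 2700.0
        mask = np.isfinite(tau)
        # add unmasked pixels to label 2's footprint: mean_tau must not move
        labels_grown = labels.copy()
        labels_grown[5, 1:5] = 2
        lm = lifetime_map_from(tau, mask, np.ones((10, 10)))
        recs = {r.label: r for r in nucleus_stats(labels, lm)}
        recs_grown = {r.label: r for r in nucleus_stats(labels_grown, lm)}
        assert recs[2].mean_tau == recs_grown[2].mean_tau == 2400.0
        # relabeling (swap 1 and 2) permutes records but not their stats
        swapped = np.where(labels == 1, 2, np.where(labels == 2, 1, 0))
        recs_swapped = {r.label: r for r in nucleus_stats(swapped, lm)}
        assert recs_swapped[1].mean_tau == recs[2].mean_tau

    def test_nucleus_without_masked_tau_reports_nan(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[0:2, 0:2] = 1
        tau = np.full((6, 6), np.nan)
        lm = lifetime_map_from(tau, np.zeros((6, 6), bool), np.ones((6, 6)))
        (rec,) = nucleus_stats(labels, lm)
        assert np.isnan(rec.mean_tau)

    def test_grid_mismatch_raises(self):
        lm = lifetime_map_from(np.full((6, 6), np.nan), np.zeros((6, 6), bool), np.ones((6, 6)))
        with pytest.raises(ValueError):
            nucleus_stats(np.zeros((4, 4), dtype=int), lm)

    def test_records_frame_columns(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[1:4, 1:4] = 1
        tau = np.where(labels == 1, 2500.0, np.nan)
        lm = lifetime_map_from(tau, labels == 1, np.ones((6, 6)))
        frame = records_to_frame(nucleus_stats(labels, lm))
        assert list(frame.columns) == [
            "label", "area_px", "mean_tau_ps", "mean_if", "centroid_row", "centroid_col",
        ]


class TestRegistration:
    @pytest.fixture
    def phantom_channels(self):
        cfg = SimConfig(
            image_size=128, nucleus_radius=40.0, n_foci=8, focus_radius=4.0,
            axis=default_axis(64), seed=9,
        )
        ph = make_phantom(cfg)
        if_small = simulate_if_image(ph, seed=9)
        if_big = resize(if_small, (512, 512), order=3)
        return ph.brightness_map.astype(float), if_big

    def test_output_on_target_grid(self, phantom_channels):
        flim, if_big = phantom_channels
        registered, info = register_if_to_flim(if_big, (128, 128), flim)
        assert registered.shape == (128, 128)

    def test_aligned_input_recovers_near_identity(self, phantom_channels):
        flim, if_big = phantom_channels
        _, info = register_if_to_flim(if_big, (128, 128), flim)
        ty, tx = info["translation"]
        assert abs(ty) <= 0.5 and abs(tx) <= 0.5
        assert abs(info["rotation_deg"]) <= 0.5

    def test_known_shift_recovered(self, phantom_channels):
        flim, if_big = phantom_channels
        shifted = np.roll(if_big, (12, 12), axis=(0, 1))  # 3 px on the 128 grid
        _, info = register_if_to_flim(shifted, (128, 128), flim)
        ty, tx = info["translation"]
        assert ty == pytest.approx(-3.0, abs=0.5)
        assert tx == pytest.approx(-3.0, abs=0.5)

    def test_undersized_if_image_rejected(self, phantom_channels):
        flim, _ = phantom_channels
        with pytest.raises(ValueError):
            register_if_to_flim(np.ones((64, 64)), (128, 128), flim)


class TestLineProfile:
    def test_constant_images_give_flat_profiles(self):
        a = np.full((32, 32), 5.0)
        b = np.full((32, 32), 9.0)
        prof = line_profile(a, b, ((10.0, 2.0), (10.0, 28.0)), width=2)
        np.testing.assert_allclose(prof.values_a, 5.0)
        np.testing.assert_allclose(prof.values_b, 9.0)

    def test_step_edge_located_within_one_pixel(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 10.0  # vertical step at column 16
        prof = line_profile(img, img, ((15.0, 4.0), (15.0, 28.0)), width=2)
        crossing = prof.arc[np.argmax(prof.values_a >= 5.0)]  # first half-height sample
        # arc position of the analytic edge: column 15.5 - start column 4
        assert crossing == pytest.approx(15.5 - 4.0, abs=1.0)

    def test_endpoints_outside_image_rejected(self):
        img = np.zeros((16, 16))
        with pytest.raises(ValueError):
            line_profile(img, img, ((0.0, 0.0), (20.0, 20.0)))

    def test_focus_profile_anticorrelates_if_and_tau(self):
        # heterochromatin focus: IF peak where the lifetime dips
        cfg = SimConfig(image_size=96, nucleus_radius=30.0, n_foci=5, focus_radius=4.0,
                        axis=default_axis(64), seed=13)
        from chromaflim.synthgen import focus_profile_endpoints

        ph = make_phantom(cfg)
        if_img = simulate_if_image(ph, seed=13)
        tau_img = np.where(ph.state_map > 0, ph.tau_map, 0.0)
        start, end = focus_profile_endpoints(ph, length=20.0)
        prof = line_profile(if_img, tau_img, (start, end), width=2)
        assert prof.correlation() < 0

    def test_suggested_line_centers_on_brightest_focus(self):
        img = np.zeros((40, 40))
        img[20, 25] = 100.0
        start, end = suggest_profile_line(img, length=10.0)
        assert start[0] == end[0] == 20.0
        assert (start[1] + end[1]) / 2 == pytest.approx(25.0, abs=1.0)

    def test_width_one_matches_single_row_samples(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(size=(16, 16))
        prof = line_profile(img, img, ((8.0, 1.0), (8.0, 14.0)), width=1)
        np.testing.assert_allclose(prof.values_a, img[8, 1:15], rtol=1e-12)
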