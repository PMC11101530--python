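"""Generators: determinism, ground-truth fidelity and noise calibration."""

import math

import numpy as np
import pytest
from skimage.morphology import skeletonize

import oracle_utils as oracle
from mpecmorph.synthetic_data import (
    SceneSpec,
    TimeSeriesSpec,
    make_filament_mask,
    make_pellet_mask,
    make_scene,
    make_timeseries,
)


class TestPelletMask:
    def test_plain_disk_area_and_convexity(self):
        m = make_pellet_mask(50.0, 0.0, 1.0, 1.0, seed=1)
        assert m.n_pixels == pytest.approx(math.pi * 50**2, rel=0.02)

    def test_deterministic_for_fixed_seed(self):
        a = make_pellet_mask(40.0, 0.2, 1.5, 1.0, seed=7)
        b = make_pellet_mask(40.0, 0.2, 1.5, 1.0, seed=7)
        assert np.array_equal(a.pixels, b.pixels)
        c = make_pellet_mask(40.0, 0.2, 1.5, 1.0, seed=8)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_subpixel_radius_errors(self):
        with pytest.raises(ValueError):
            make_pellet_mask(1.0, 0.0, 1.0, 2.0, seed=0)  # 0.5 px radius

    @pytest.mark.parametrize("rough,aspect", [(-0.1, 1.0), (1.0, 1.0), (0.1, 0.5)])
    def test_invalid_shape_parameters_error(self, rough, aspect):
        with pytest.raises(ValueError):
            make_pellet_mask(30.0, rough, aspect, 1.0, seed=0)

    def test_rough_pellets_are_connected_by_construction(self):
        # construction is star-convex, so ObjectMask validation passes
        for seed in range(5):
            make_pellet_mask(30.0, 0.3, 2.0, 1.0, seed=seed)

    def test_calibration_scales_pixel_size(self):
        fine = make_pellet_mask(50.0, 0.0, 1.0, 0.5, seed=1)
        coarse = make_pellet_mask(50.0, 0.0, 1.0, 2.0, seed=1)
        assert fine.n_pixels == pytest.approx(4 * math.pi * 50**2, rel=0.02)
        assert coarse.n_pixels == pytest.approx(math.pi * 25**2, rel=0.04)


class TestFilamentMask:
    def test_straight_filament_is_strongly_elongated(self):
        m = make_filament_mask(100.0, 3.0, 0.0, 1.0, seed=2)
        assert oracle.brute_elongation(m.pixels) >= 4.0

    def test_spans_at_least_80_percent_of_length(self):
        for seed in range(5):
            m = make_filament_mask(80.0, 3.0, 0.0, 1.0, seed=seed)
            assert oracle.brute_feret(m.pixels) >= 0.8 * 80.0

    def test_area_bounded_by_length_width_envelope(self):
        for seed in range(5):
            m = make_filament_mask(60.0, 3.0, 1.0, 1.0, seed=seed)
            assert m.n_pixels <= 60.0 * 3.0 * 1.8

    def test_unbranched_skeleton_when_branch_probability_zero(self):
        m = make_filament_mask(60.0, 3.0, 0.0, 1.0, seed=3)
        patch, _ = m.to_patch()
        skel = skeletonize(patch)
        # no skeleton pixel may have more than 2 neighbours
        from scipy.ndimage import convolve

        neighbours = convolve(skel.astype(int), np.ones((3, 3), int), mode="constant")
        assert ((neighbours - 1)[skel] <= 2).all()

    def test_deterministic_for_fixed_seed(self):
        a = make_filament_mask(50.0, 2.5, 0.5, 1.0, seed=11)
        b = make_filament_mask(50.0, 2.5, 0.5, 1.0, seed=11)
        assert np.array_equal(a.pixels, b.pixels)

    def test_subpixel_width_errors(self):
        with pytest.raises(ValueError):
            make_filament_mask(50.0, 0.4, 0.0, 1.0, seed=0)

    def test_width_longer_than_length_errors(self):
        with pytest.raises(ValueError):
            make_filament_mask(2.0, 3.0, 0.0, 1.0, seed=0)


class TestScene:
    def test_requested_object_counts_in_ground_truth(self):
        spec = SceneSpec(n_pellets=5, n_clumps=0, n_spores=0, n_talc=0,
                         pellet_radius_um=(40.0, 60.0), image_shape=(700, 700), seed=1)
        _, truth = make_scene(spec)
        assert len(truth.objects) == 5
        assert all(o.class_label == "pellet" for o in truth.objects)

    def test_bit_identical_for_same_spec(self):
        spec = SceneSpec(n_pellets=2, n_clumps=3, seed=5, image_shape=(512, 512),
                         pellet_radius_um=(40.0, 80.0), noise_sd=0.02)
        img1, t1 = make_scene(spec)
        img2, t2 = make_scene(spec)
        assert np.array_equal(img1.data, img2.data)
        assert t1.objects == t2.objects

    def test_aspect_ratio_reflected_in_second_moments(self):
        spec = SceneSpec(n_pellets=4, n_clumps=0, pellet_aspect=(2.0, 2.0),
                         pellet_roughness=(0.0, 0.0), pellet_radius_um=(50.0, 70.0),
                         image_shape=(900, 900), seed=3)
        image, truth = make_scene(spec)
        # oracle: direct second-moment sums over the dark pixels of each object
        dark = image.data < 0.6
        from scipy import ndimage

        labels, n = ndimage.label(dark, structure=np.ones((3, 3), bool))
        assert n == 4
        for lab in range(1, n + 1):
            pix = np.column_stack(np.nonzero(labels == lab))
            assert oracle.brute_elongation(pix) == pytest.approx(4.0, rel=0.05)

    def test_objects_dark_on_bright_background(self):
        spec = SceneSpec(n_pellets=2, n_clumps=2, seed=6, image_shape=(512, 512),
                         pellet_radius_um=(40.0, 60.0))
        image, _ = make_scene(spec)
        assert np.median(image.data) == pytest.approx(spec.background)
        assert image.data.min() < spec.object_intensity + 0.1

    def test_overcrowded_scene_errors_with_class_name(self):
        spec = SceneSpec(n_pellets=40, image_shape=(256, 256),
                         pellet_radius_um=(60.0, 80.0), seed=0)
        with pytest.raises(RuntimeError, match="pellet"):
            make_scene(spec)

    def test_class_realism_of_default_ranges(self):
        # pellets land in the 1e4-1e6 µm² band, clumps stay below 164 µm²
        for seed in (1, 2, 3):
            spec = SceneSpec(n_pellets=2, n_clumps=6, seed=seed,
                             image_shape=(1024, 1024))
            _, truth = make_scene(spec)
            for o in truth.of_class("pellet"):
                assert 1e4 <= o.true_area_um2 <= 1e6
            for o in truth.of_class("clump_hyphae"):
                assert o.true_area_um2 <= 164.0

    def test_ground_truth_area_close_to_rendered_pixels(self):
        spec = SceneSpec(n_pellets=3, n_clumps=0, seed=8, image_shape=(1024, 1024))
        image, truth = make_scene(spec)
        dark = image.data < 0.6
        from scipy import ndimage

        labels, n = ndimage.label(dark, structure=np.ones((3, 3), bool))
        assert n == 3
        for lab in range(1, n + 1):
            pix = np.column_stack(np.nonzero(labels == lab))
            c = pix.mean(axis=0)
            truth_obj = min(
                truth.objects,
                key=lambda o: (o.centroid_rc[0] - c[0]) ** 2 + (o.centroid_rc[1] - c[1]) ** 2,
            )
            if pix.shape[0] >= 100:
                assert pix.shape[0] == pytest.approx(truth_obj.true_area_um2, rel=0.05)

    def test_spec_roundtrip_through_dict(self):
        spec = SceneSpec(n_pellets=1, seed=4)
        assert SceneSpec.from_dict(spec.to_dict()) == spec


class TestTimeSeries:
    def test_noiseless_series_scales_exactly_by_true_ef(self):
        spec = TimeSeriesSpec(cv=0.0, glucose_noise_sd=0.0, replicates=1, seed=0)
        series = {(s.talc_g_per_l, s.replicate): s for s in make_timeseries(spec)}
        control = series[(0.0, 1)]
        treated = series[(5.0, 1)]
        for m in spec.metabolites:
            for i, t in enumerate(spec.times_h):
                expect = spec.true_ef(5.0, m, t) * control.amounts[m][i]
                assert treated.amounts[m][i] == pytest.approx(expect, rel=1e-12)

    def test_unit_ef_means_identically_distributed_groups(self):
        spec = TimeSeriesSpec(
            metabolites=("oxytetracycline",),
            conditions=(0.0, 5.0),
            ef_table={"oxytetracycline": {5.0: 1.0}},
            control_means={"oxytetracycline": (1.0, 1.0, 1.0, 1.0, 1.0)},
            replicates=400,
            cv=0.2,
            seed=12,
        )
        series = make_timeseries(spec)
        a = np.array([s.amounts["oxytetracycline"][-1] for s in series if s.talc_g_per_l == 0.0])
        b = np.array([s.amounts["oxytetracycline"][-1] for s in series if s.talc_g_per_l == 5.0])
        assert a.mean() == pytest.approx(b.mean(), rel=0.05)
        assert a.std() == pytest.approx(b.std(), rel=0.15)

    def test_lognormal_noise_reproduces_requested_cv(self):
        spec = TimeSeriesSpec(
            metabolites=("oxytetracycline",),
            conditions=(0.0,),
            control_means={"oxytetracycline": (10.0, 10.0, 10.0, 10.0, 10.0)},
            replicates=1000,
            cv=0.2,
            glucose_noise_sd=0.0,
            seed=21,
        )
        series = make_timeseries(spec)
        vals = np.array([s.amounts["oxytetracycline"][0] for s in series])
        assert vals.std(ddof=1) / vals.mean() == pytest.approx(0.2, rel=0.10)
        assert vals.mean() == pytest.approx(10.0, rel=0.05)

    def test_noiseless_glucose_curves_monotone_and_match_finals(self):
        spec = TimeSeriesSpec()
        times = np.array(spec.times_h)
        for cond in spec.conditions:
            c = spec.glucose_curve(cond, times)
            assert (np.diff(c) <= 0).all()
            assert c[0] == pytest.approx(22.0)
            assert c[-1] == pytest.approx(spec.glucose_params[cond][0])

    def test_noisy_glucose_clipped_non_negative(self):
        spec = TimeSeriesSpec(glucose_noise_sd=30.0, seed=2)  # absurd noise
        for s in make_timeseries(spec):
            assert (s.glucose_g_per_l >= 0).all()

    def test_deterministic_for_fixed_seed(self):
        a = make_timeseries(TimeSeriesSpec(seed=9))
        b = make_timeseries(TimeSeriesSpec(seed=9))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.glucose_g_per_l, sb.glucose_g_per_l)
            for m in sa.metabolites:
                assert np.array_equal(sa.amounts[m], sb.amounts[m])

    def test_non_positive_control_mean_rejected(self):
        with pytest.raises(ValueError):
            TimeSeriesSpec(
                metabolites=("oxytetracycline",),
                control_means={"oxytetracycline": (0.0, 1.0, 1.0, 1.0, 1.0)},
            )
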