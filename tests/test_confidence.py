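import numpy as np
import pytest

from fatseg.confidence import (
    ConfidenceConfig,
    ConfidenceImage,
    build_confidence_image,
    confidence_weight,
    extract_fat,
    find_t2_modes,
    mean_shift_1d,
    run_pipeline,
    score_regions,
)
from fatseg.io_formats import AcquisitionDescriptor
from fatseg.segment import RegionLabelMap
from fatseg.synthdata import generate_stack, mouse_config
from fatseg.t2fit import T2FitResult


def make_fit_result(t2_map, valid=None):
    t2_map = np.asarray(t2_map, dtype=float)
    valid = np.ones_like(t2_map, dtype=bool) if valid is None else valid
    return T2FitResult(
        s0_map=np.full_like(t2_map, 1000.0),
        t2_map=t2_map,
        valid_mask=valid,
        residual_map=np.zeros_like(t2_map),
    )


class TestConfidenceKernel:
    def test_weight_is_one_at_mode(self):
        res = make_fit_result([[60.0]])
        img = build_confidence_image(res, mode_t2=60.0, sigma_snr=3.0)
        assert img.weights[0, 0] == 1.0

    def test_four_sigma_weight_is_negligible(self):
        res = make_fit_result([[60.0 + 4 * 3.0]])
        img = build_confidence_image(res, mode_t2=60.0, sigma_snr=3.0)
        assert img.weights[0, 0] == pytest.approx(np.exp(-8.0), rel=1e-12)
        assert img.weights[0, 0] < 4e-4

    def test_halving_sigma_decreases_off_mode_weight(self):
        res = make_fit_result([[50.0, 55.0, 70.0]])
        wide = build_confidence_image(res, 60.0, sigma_snr=6.0).weights
        narrow = build_confidence_image(res, 60.0, sigma_snr=3.0).weights
        assert (narrow < wide).all()

    def test_monotone_in_distance_from_mode(self):
        t2 = np.linspace(60, 100, 50)[None, :]
        w = build_confidence_image(make_fit_result(t2), 60.0, 4.0).weights[0]
        assert (np.diff(w) < 0).all()

    def test_invalid_pixels_get_zero_weight(self):
        valid = np.array([[True, False]])
        img = build_confidence_image(make_fit_result([[60.0, 60.0]], valid), 60.0, 3.0)
        np.testing.assert_array_equal(img.weights, [[1.0, 0.0]])

    def test_bounded_in_unit_interval(self, rng):
        t2 = rng.uniform(1, 200, size=(20, 20))
        w = build_confidence_image(make_fit_result(t2), 60.0, 5.0).weights
        assert (w >= 0).all() and (w <= 1).all()
        assert (w == 1).sum() == 0  # only exact mode hits give 1

    def test_literal_single_power_denominator_option(self):
        res = make_fit_result([[65.0]])
        squared = build_confidence_image(res, 60.0, 2.0, squared_sigma=True).weights[0, 0]
        literal = build_confidence_image(res, 60.0, 2.0, squared_sigma=False).weights[0, 0]
        assert squared == pytest.approx(np.exp(-25 / 8))
        assert literal == pytest.approx(np.exp(-25 / 4))


class TestFindModes:
    def test_two_component_mixture(self, rng):
        vals = np.concatenate([rng.normal(25, 2, 500), rng.normal(60, 2, 500)])
        modes = find_t2_modes(vals.reshape(20, 50), np.ones((20, 50), bool), bandwidth=5.0)
        assert len(modes) == 2
        assert abs(modes[0] - 25) < 1.0
        assert abs(modes[1] - 60) < 1.0

    def test_degenerate_distribution_single_mode(self):
        modes = find_t2_modes(np.full((4, 4), 40.0), np.ones((4, 4), bool), 5.0)
        np.testing.assert_allclose(modes, [40.0])

    def test_trajectories_match_stepwise_reference(self, rng):
        data = rng.uniform(20, 80, 50)
        bw = 5.0
        ours = mean_shift_1d(data.copy(), data, bw, max_iterations=40, tol_factor=0.0)
        for k in [0, 10, 30, 49]:
            x = data[k]
            for _ in range(40):  # independent scalar iteration
                w = np.array([np.exp(-((x - t) ** 2) / (2 * bw**2)) for t in data])
                x = float(np.sum(w * data) / np.sum(w))
            assert ours[k] == pytest.approx(x, abs=1e-10)

    def test_requires_enough_valid_pixels(self):
        with pytest.raises(ValueError):
            find_t2_modes(np.full((2, 2), 40.0), np.ones((2, 2), bool), 5.0)


def region_map(labels):
    labels = np.asarray(labels)
    n = labels.max()
    sizes = np.array([(labels == r).sum() for r in range(1, n + 1)])
    return RegionLabelMap(labels, np.zeros((n, 3)), sizes)


class TestScoreRegions:
    cfg = ConfidenceConfig()

    def conf(self, weights):
        return ConfidenceImage(np.asarray(weights, dtype=float), 20.0, 3.0, 60.0)

    def test_uniform_region_sum_and_mean(self):
        labels = np.ones((2, 5), dtype=int)
        scores = score_regions(self.conf(np.ones((2, 5))), region_map(labels), self.cfg)
        assert scores.score_sum[0] == pytest.approx(10.0)
        assert scores.score_mean[0] == pytest.approx(1.0)

    def test_invalid_region_scores_zero(self):
        labels = np.array([[1, 1], [2, 2]])
        w = np.array([[0.0, 0.0], [0.5, 0.7]])
        scores = score_regions(self.conf(w), region_map(labels), self.cfg)
        assert scores.score_sum[0] == 0.0
        assert scores.score_mean[1] == pytest.approx(0.6)

    def test_hand_built_four_region_fixture(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[:4, :4], labels[:4, 4:], labels[4:, :4], labels[4:, 4:] = 1, 2, 3, 4
        w = np.zeros((8, 8))
        w[:4, :4] = 0.9
        w[:4, 4:] = 0.25
        w[4:, :4] = np.tile([0.0, 1.0], (4, 2))
        w[4:, 4:] = 0.05
        scores = score_regions(self.conf(w), region_map(labels), self.cfg)
        np.testing.assert_allclose(scores.score_sum, [16 * 0.9, 16 * 0.25, 8.0, 16 * 0.05])
        np.testing.assert_allclose(scores.score_mean, [0.9, 0.25, 0.5, 0.05])
        assert scores.to_frame().shape[0] == 4


class TestExtractFat:
    descriptor = AcquisitionDescriptor(8.3, 10, field_of_view=(40.0, 40.0), slice_thickness=0.9)

    def setup_method(self):
        self.labels = np.array([[1, 1, 2, 2]] * 4)
        self.regions = region_map(self.labels)
        w = np.where(self.labels == 1, 0.9, 0.1)
        self.scores = score_regions(
            ConfidenceImage(w, 20.0, 3.0, 60.0), self.regions, ConfidenceConfig()
        )

    def test_zero_threshold_includes_all_regions(self):
        out = extract_fat(self.scores, self.regions, 0.0, self.descriptor)
        assert out.mask.all()

    def test_threshold_above_max_gives_empty_mask(self):
        out = extract_fat(self.scores, self.regions, 0.95, self.descriptor)
        assert not out.mask.any()
        assert out.area_pixels == 0 and out.volume_mm3 == 0.0

    def test_separating_threshold_selects_high_region(self):
        out = extract_fat(self.scores, self.regions, 0.5, self.descriptor)
        np.testing.assert_array_equal(out.mask, self.labels == 1)
        assert out.area_pixels == 8
        assert out.volume_mm3 == pytest.approx(8 * 10.0 * 10.0 * 0.9)

    def test_area_non_increasing_in_threshold(self):
        areas = [
            extract_fat(self.scores, self.regions, t, self.descriptor).area_pixels
            for t in np.linspace(0, 1, 11)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestPipeline:
    def test_noiseless_separable_scene_recovered_exactly(self, calibration_curve):
        cfg = mouse_config(64, target_snr=None, partial_volume_blur_sigma=0.0,
                           bias_field_amplitude=0.0)
        stack, _, fat_gt = generate_stack(cfg)
        res = run_pipeline(stack, calibration_curve)
        np.testing.assert_array_equal(res.fat_mask, fat_gt)
        assert res.fat_mode_t2 == pytest.approx(60.0, abs=0.5)

    def test_rerun_is_bit_identical(self, calibration_curve):
        stack, _, _ = generate_stack(mouse_config(64, target_snr=20.0, rng_seed=3))
        a = run_pipeline(stack, calibration_curve)
        b = run_pipeline(stack, calibration_curve)
        np.testing.assert_array_equal(a.fat_mask, b.fat_mask)
        np.testing.assert_array_equal(a.confidence.weights, b.confidence.weights)
        np.testing.assert_array_equal(a.t2_result.t2_map, b.t2_result.t2_map)
        assert a.snr == b.snr and a.sigma_snr == b.sigma_snr

    def test_outputs_are_persisted(self, calibration_curve, tmp_path):
        stack, _, _ = generate_stack(mouse_config(64, target_snr=20.0, rng_seed=3))
        run_pipeline(stack, calibration_curve, out_dir=tmp_path)
        for name in ("t2map.nii", "confidence.nii", "labels.nii", "fat_mask.nii",
                     "scores.csv", "summary.json"):
            assert (tmp_path / name).exists()
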