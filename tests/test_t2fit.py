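import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatseg.io_formats import EchoStack
from fatseg.t2fit import (
    DecayModelParams,
    FitConfig,
    baseline_subtract,
    compare_echo_subsets,
    estimate_baseline_threshold,
    fit_pixel,
    fit_stack,
    merit,
    model_signal,
)


def make_signal(s0, t2, descriptor):
    return s0 * np.exp(-descriptor.echo_times / t2)


class TestModelSignal:
    def test_closed_form_value(self):
        v = model_signal(DecayModelParams(1000, 40), echo_index=1, te_spacing=8.3)
        assert v == pytest.approx(1000 * math.exp(-8.3 / 40), rel=1e-12)

    def test_zero_spacing_limit_is_s0(self):
        assert model_signal(DecayModelParams(777, 33), 5, 0.0) == pytest.approx(777)

    def test_strictly_decreasing_in_echo_index(self):
        vals = [model_signal(DecayModelParams(500, 20), i, 8.3) for i in range(1, 11)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_matches_independent_tabulation(self):
        # spreadsheet-style recomputation of the exponential, term by term
        expected = [500 * math.exp(-(i * 8.3) / 20) for i in range(1, 11)]
        got = [model_signal(DecayModelParams(500, 20), i, 8.3) for i in range(1, 11)]
        np.testing.assert_allclose(got, expected, rtol=1e-14)

    def test_non_positive_t2_rejected(self):
        with pytest.raises(ValueError):
            DecayModelParams(1000, -5)


class TestBaselineSubtract:
    def test_keeps_points_above_threshold(self):
        sig = [900, 700, 500, 300, 200, 150, 100, 80, 60, 50]
        idx = baseline_subtract(np.array(sig), threshold=70, min_valid_points=5)
        np.testing.assert_array_equal(idx, np.arange(8))

    def test_below_minimum_returns_empty(self):
        sig = [100, 60, 30, 20, 10, 8, 5, 4, 3, 2]
        assert baseline_subtract(np.array(sig), 50, 5).size == 0

    def test_zero_threshold_keeps_everything(self):
        sig = np.arange(10, 0, -1, dtype=float)
        np.testing.assert_array_equal(baseline_subtract(sig, 0, 5), np.arange(10))

    def test_background_rms_threshold(self):
        bg = np.array([3.0, -3.0, 3.0, -3.0])
        assert estimate_baseline_threshold(bg) == pytest.approx(9.0)


class TestFitPixel:
    @pytest.mark.parametrize("method", ["ls", "wls"])
    def test_exact_recovery_on_noiseless_signal(self, descriptor, method):
        sig = make_signal(1000, 40, descriptor)
        p = fit_pixel(sig, descriptor, FitConfig(method=method))
        assert p is not None
        assert p.s0 == pytest.approx(1000, rel=1e-6)
        assert p.t2 == pytest.approx(40, rel=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(s0=st.floats(100, 5000), t2=st.floats(5, 150))
    def test_exact_recovery_property(self, s0, t2):
        from fatseg.io_formats import AcquisitionDescriptor

        descriptor = AcquisitionDescriptor(te_spacing=8.3, n_echoes=10)
        sig = make_signal(s0, t2, descriptor)
        p = fit_pixel(sig, descriptor, FitConfig(method="wls"))
        assert p is not None
        assert abs(p.s0 - s0) / s0 < 1e-6
        assert abs(p.t2 - t2) / t2 < 1e-6

    def test_too_few_valid_points_is_invalid(self, descriptor):
        sig = make_signal(1000, 10, descriptor)  # fast decay
        thr = sig[3] - 1e-9  # exactly 4 points above threshold
        assert (sig >= thr).sum() == 4
        assert fit_pixel(sig, descriptor, FitConfig(baseline_threshold=thr)) is None

    def test_trimmed_t2_is_invalid(self, descriptor):
        sig = make_signal(1000, 500, descriptor)
        assert fit_pixel(sig, descriptor, FitConfig(t2_trim_max=200)) is None

    def test_wls_beats_brute_force_grid(self, descriptor, rng):
        """The WLS optimum's merit is below every point of a dense grid."""
        sig = make_signal(1000, 40, descriptor) + rng.normal(0, 20, 10)
        cfg = FitConfig(method="wls", baseline_threshold=0.0)
        p = fit_pixel(sig, descriptor, cfg)
        idx = baseline_subtract(sig, 0.0, cfg.min_valid_points)
        fitted = merit(sig, idx, p, descriptor, "wls")
        s0_grid = np.arange(500, 1501, 4.0)
        t2_grid = np.arange(10, 100.0001, 0.2)
        te = descriptor.echo_times[idx]
        data = sig[idx]
        w = data
        best = np.inf
        for t2 in t2_grid:
            model = np.exp(-te / t2)[None, :] * s0_grid[:, None]
            best = min(best, float(np.min(np.sum(w * (data - model) ** 2, axis=1))))
        assert fitted <= best + 1e-9 * (1 + best)
        # and the grid's argmin is within a grid step of the fitted optimum
        assert abs(p.t2 - 40) < 5  # sanity: near the true value


class TestFitStack:
    def test_two_compartment_exact(self, descriptor):
        img_t2 = np.full((8, 8), 25.0)
        img_t2[:, 4:] = 60.0
        data = 1000 * np.exp(-descriptor.echo_times[:, None, None] / img_t2[None])
        res = fit_stack(EchoStack(data, descriptor), FitConfig(method="wls"))
        assert res.valid_mask.all()
        np.testing.assert_allclose(res.t2_map, img_t2, rtol=1e-9)

    def test_all_zero_stack_is_invalid(self, descriptor):
        res = fit_stack(EchoStack(np.zeros((10, 6, 6)), descriptor), FitConfig())
        assert not res.valid_mask.any()
        assert (res.t2_map == -1.0).all()

    def test_matches_isolated_fit_pixel(self, descriptor, rng):
        data = 1000 * np.exp(-descriptor.echo_times[:, None, None] / 40.0)
        data = data + rng.normal(0, 25, size=(10, 5, 5))
        stack = EchoStack(np.abs(data), descriptor)
        cfg = FitConfig(method="wls", baseline_threshold=30.0)
        res = fit_stack(stack, cfg)
        for i in range(5):
            for j in range(5):
                p = fit_pixel(stack.data[:, i, j], descriptor, cfg)
                if p is None:
                    assert not res.valid_mask[i, j]
                else:
                    assert res.valid_mask[i, j]
                    assert res.t2_map[i, j] == pytest.approx(p.t2, rel=1e-9)
                    assert res.s0_map[i, j] == pytest.approx(p.s0, rel=1e-9)

    def test_no_valid_pixel_exceeds_trim(self, descriptor, rng):
        data = np.abs(rng.normal(100, 80, size=(10, 12, 12)))
        res = fit_stack(EchoStack(data, descriptor), FitConfig(t2_trim_max=200))
        assert (res.t2_map[res.valid_mask] <= 200).all()

    def test_roi_shape_mismatch(self, descriptor):
        stack = EchoStack(np.ones((10, 6, 6)), descriptor)
        with pytest.raises(ValueError):
            fit_stack(stack, FitConfig(), roi=np.ones((4, 4), dtype=bool))


class TestCompareEchoSubsets:
    def test_noiseless_means_identical_across_k(self, lard_stack):
        stack, labels = lard_stack
        table = compare_echo_subsets(stack, labels > 0, FitConfig(), [5, 7, 10])
        for method in ("ls", "wls"):
            means = table[table.method == method].mean_t2.to_numpy()
            np.testing.assert_allclose(means, 55.0, rtol=1e-8)

    def test_single_count_matches_fit_stack(self, lard_stack):
        stack, labels = lard_stack
        roi = labels > 0
        table = compare_echo_subsets(stack, roi, FitConfig(), [10])
        res = fit_stack(stack, FitConfig(method="wls"), roi)
        row = table[(table.method == "wls")].iloc[0]
        assert row.mean_t2 == pytest.approx(float(res.t2_map[res.valid_mask].mean()))
        assert row.n_valid == int(res.valid_mask.sum())

    def test_rejects_bad_inputs(self, lard_stack):
        stack, labels = lard_stack
        with pytest.raises(ValueError):
            compare_echo_subsets(stack, np.zeros_like(labels, dtype=bool), FitConfig(), [5])
        with pytest.raises(ValueError):
            compare_echo_subsets(stack, labels > 0, FitConfig(), [1])
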