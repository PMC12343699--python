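"""Threshold bands and detection rules."""

import numpy as np
import pytest

import permclean as pc
from permclean.detection import (DEFAULT_B, band_for, iqr_normal_width,
                                 mad_normal_constant,
                                 min_window_for_threshold_factor,
                                 three_sigma_coverage_percent)
from permclean.errors import ParameterError


class TestStatic:
    def test_exceeding_the_threshold_flags(self):
        spec = pc.ThresholdSpec()
        assert spec.static_value == pytest.approx(1.06)
        assert pc.static_decide(1.07, spec)

    def test_zero_is_clean(self):
        assert not pc.static_decide(0.0, pc.ThresholdSpec())

    def test_two_sided_catches_drops(self):
        spec = pc.ThresholdSpec()
        assert pc.static_decide(-1.20, spec)
        one_sided = pc.ThresholdSpec(two_sided=False)
        assert not pc.static_decide(-1.20, one_sided)


class TestBands:
    def test_three_sigma_identical_values_collapse(self):
        band = pc.band_three_sigma(np.full(12, 5.0))
        assert (band.lower, band.center, band.upper) == (5.0, 5.0, 5.0)

    def test_three_sigma_hand_computation(self):
        band = pc.band_three_sigma(np.arange(1.0, 11.0), factor=3.0)
        assert band.center == pytest.approx(5.5)
        sd = np.arange(1.0, 11.0).std(ddof=1)
        assert sd == pytest.approx(3.02765, abs=1e-5)
        assert band.lower == pytest.approx(5.5 - 3 * sd)
        assert band.upper == pytest.approx(14.583, abs=1e-3)

    def test_hampel_hand_computation(self):
        band = pc.band_hampel([1, 2, 3, 4, 100], factor=3.0, b=DEFAULT_B)
        assert band.center == pytest.approx(3.0)
        assert band.lower == pytest.approx(-1.4478, abs=1e-4)
        assert band.upper == pytest.approx(7.4478, abs=1e-4)
        assert not (band.lower <= 100 <= band.upper)

    def test_hampel_symmetric_window_centres_on_zero(self):
        band = pc.band_hampel([-3, -1, 0, 1, 3])
        assert band.center == 0.0

    def test_iqr_hand_computation(self):
        band = pc.band_iqr([1, 2, 3, 4, 5], factor=2.0)
        assert band.center == pytest.approx(3.0)
        assert band.lower == pytest.approx(-1.0)
        assert band.upper == pytest.approx(7.0)

    def test_collapsed_bands_for_identical_windows(self):
        for fn in (pc.band_hampel, pc.band_iqr):
            band = fn(np.full(8, 2.5))
            assert band.lower == band.center == band.upper == 2.5

    def test_iqr_estimates_sigma_for_normal_data(self):
        rng = np.random.default_rng(314)
        x = rng.normal(size=100_000)
        q1, q3 = np.quantile(x, [0.25, 0.75])
        assert (q3 - q1) / 1.35 == pytest.approx(x.std(ddof=1), rel=0.05)

    @pytest.mark.parametrize("kind", ["three_sigma", "hampel", "iqr"])
    def test_affine_equivariance(self, kind, rng):
        spec = pc.ThresholdSpec(kind=kind, w3=12)
        x = rng.normal(size=12)
        a, c = 2.5, -7.0
        b0 = band_for(x, spec)
        b1 = band_for(a * x + c, spec)
        assert b1.center == pytest.approx(a * b0.center + c, abs=1e-9)
        assert b1.lower == pytest.approx(a * b0.lower + c, abs=1e-9)
        assert b1.upper == pytest.approx(a * b0.upper + c, abs=1e-9)

    def test_hampel_narrower_than_three_sigma_under_contamination(self, rng):
        """One gross outlier inflates the sigma band but not the Hampel band
        (masking vs robustness)."""
        x = rng.normal(size=30)
        x[13] = 50.0
        bh = pc.band_hampel(x)
        bs = pc.band_three_sigma(x)
        assert bh.upper - bh.lower < bs.upper - bs.lower


class TestDynamic:
    def test_inside_band_is_clean(self, rng):
        spec = pc.ThresholdSpec(kind="three_sigma", w3=50)
        window = rng.normal(size=50)
        assert not pc.dynamic_decide(float(window.mean()), window, spec)

    def test_collapsed_band_flags_nonzero_deviation(self):
        spec = pc.ThresholdSpec(kind="three_sigma", w3=120)
        assert pc.dynamic_decide(0.5, np.zeros(120), spec)
        assert not pc.dynamic_decide(0.0, np.zeros(120), spec)

    @pytest.mark.parametrize("kind", ["three_sigma", "hampel", "iqr"])
    def test_gross_outlier_flagged_by_all_kinds(self, kind):
        rng = np.random.default_rng(77)
        window = rng.normal(size=150)
        spec = pc.ThresholdSpec(kind=kind, w3=150)
        assert pc.dynamic_decide(10.0, window, spec)

    def test_warmup_never_flags(self):
        spec = pc.ThresholdSpec(kind="hampel", w3=30)
        assert not pc.dynamic_decide(1e6, np.zeros(29), spec)

    def test_min_scale_floor_widens_collapsed_band(self):
        spec = pc.ThresholdSpec(kind="three_sigma", w3=20, min_scale=1.0)
        assert not pc.dynamic_decide(2.9, np.zeros(20), spec)
        assert pc.dynamic_decide(3.1, np.zeros(20), spec)

    def test_small_window_three_sigma_cannot_flag_inliers(self, rng):
        """No point of a window of size w can exceed (w-1)/sqrt(w) sigmas,
        so factor-3 bands never fire within windows of w <= 10."""
        for w in range(2, 11):
            for _ in range(20):
                window = rng.normal(size=w) * rng.uniform(0.1, 10)
                band = pc.band_three_sigma(window, factor=3.0)
                assert all(band.lower <= v <= band.upper for v in window)


class TestMaxThresholdFactor:
    def test_values(self):
        assert pc.max_threshold_factor(4) == pytest.approx(1.5)
        assert pc.max_threshold_factor(10) == pytest.approx(2.846, abs=1e-3)
        assert pc.max_threshold_factor(10) < 3

    def test_monotone_increasing(self):
        vals = [pc.max_threshold_factor(w) for w in range(2, 200)]
        assert np.all(np.diff(vals) > 0)

    def test_window_must_hold_two_points(self):
        with pytest.raises(ParameterError):
            pc.max_threshold_factor(1)


class TestNormalTheoryConstants:
    def test_mad_constant(self):
        assert mad_normal_constant() == pytest.approx(1.4826, abs=5e-5)

    def test_three_sigma_coverage(self):
        assert three_sigma_coverage_percent() == pytest.approx(99.73, abs=5e-3)

    def test_iqr_width_and_sigma_multiple(self):
        assert iqr_normal_width() == pytest.approx(1.35, abs=5e-3)
        assert pc.ThresholdSpec(kind="iqr", w3=10).factor * iqr_normal_width() \
            == pytest.approx(2.7, abs=5e-3)

    def test_minimum_window_for_three_sigma(self):
        assert min_window_for_threshold_factor(3.0) == 11
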