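"""Threshold matching, ablation prediction and group statistics."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from inspiresim.calibration import (AblationMeasurement, VolumeFieldCurve,
                                    calibrate_threshold, group_summary,
                                    linear_trend, predict_ablation,
                                    welch_t_test, welch_t_test_from_stats)
from inspiresim.invivo import REFERENCE_GROUPS


class TestCalibrateThreshold:
    def test_exact_grid_hit_returns_grid_value(self, curves):
        curve = curves[1.5]
        i = int(np.where(curve.e_grid == 600.0)[0][0])
        match = calibrate_threshold(curve, curve.volumes[i])
        assert match.threshold == pytest.approx(600.0, abs=1e-9)
        assert not match.out_of_range

    def test_round_trip_identity(self, curves):
        """calibrate o volume_at is the identity: exact in grid-nearest
        mode on grid points, within 10 V/cm interpolated."""
        curve = curves[1.5]
        for e in np.arange(300.0, 1500.0, 70.0):
            v = curve.volume_at(e)
            assert abs(calibrate_threshold(curve, v).threshold - e) < 10.0
        for i in range(10, 180, 17):
            v = curve.volumes[i]
            got = calibrate_threshold(curve, v, mode="grid-nearest").threshold
            assert got == curve.e_grid[i]

    def test_sphere_benchmark_inverts_closed_form(self, sphere_field):
        """Matching the closed-form 1.95 cm^3 volume recovers ~1000 V/cm."""
        curve = VolumeFieldCurve.from_field(sphere_field)
        match = calibrate_threshold(curve, 1.95)
        assert match.threshold == pytest.approx(1000.0, rel=0.015)

    def test_out_of_range_flagged_with_nearest_endpoint(self, curves):
        curve = curves[1.5]
        big = calibrate_threshold(curve, curve.volumes[0] * 10)
        assert big.out_of_range and big.threshold == curve.e_grid[0]
        small = calibrate_threshold(curve, curve.volumes[-1] * 0.01)
        assert small.out_of_range and small.threshold == curve.e_grid[-1]

    def test_monotone_curve_enforced(self):
        with pytest.raises(ValueError, match="non-increasing"):
            VolumeFieldCurve(np.array([1.0, 2.0, 3.0]),
                             np.array([1.0, 2.0, 0.5]))

    def test_threshold_ordering_across_geometries(self, curves):
        """At the published mean volumes the 2.0 cm geometry calibrates to
        the highest lethal threshold."""
        thr = {g.exposure_cm:
               calibrate_threshold(curves[g.exposure_cm],
                                   g.volume_mean_cm3).threshold
               for _, g in REFERENCE_GROUPS.iterrows()}
        assert thr[2.0] > thr[1.5] >= thr[1.0] >= thr[0.5]


class TestPredictAblation:
    def test_spherical_region_has_unit_elongation(self, sphere_field):
        ab = predict_ablation(sphere_field, 1000.0)
        assert ab.length_width_ratio == pytest.approx(1.0, rel=0.02)
        assert ab.volume_cm3 == pytest.approx(1.95, rel=0.02)

    def test_length_covers_exposed_electrode(self, fields):
        for exp, field in fields.items():
            ab = predict_ablation(field, 600.0)
            assert ab.length_cm >= exp

    def test_elongation_increases_with_exposure(self, fields, curves):
        ratios = []
        for _, g in REFERENCE_GROUPS.iterrows():
            thr = calibrate_threshold(curves[g.exposure_cm],
                                      g.volume_mean_cm3).threshold
            ratios.append(
                predict_ablation(fields[g.exposure_cm], thr).length_width_ratio)
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_empty_region_flagged(self, fields):
        ab = predict_ablation(fields[1.5], 1e9)
        assert ab.empty and ab.volume_cm3 == 0.0


class TestWelch:
    def test_identical_groups(self):
        r = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_summary_mode_matches_published_comparison(self):
        """1.5 vs 2.0 cm volume groups: t ~ 3.48, p ~ 0.007."""
        r = welch_t_test_from_stats(12.83, 2.61, 7, 7.64, 2.50, 5)
        assert r.statistic == pytest.approx(3.48, abs=0.01)
        assert r.df == pytest.approx(9.0, abs=0.1)
        assert r.p_value == pytest.approx(0.007, abs=0.0005)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_matches_scipy_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, rng.integers(2, 12))
        b = rng.normal(0.5, 2.0, rng.integers(2, 12))
        mine = welch_t_test(a, b)
        ref = scipy.stats.ttest_ind(a, b, equal_var=False)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=8), rng.normal(size=6)
        r1 = welch_t_test(a, b)
        r2 = welch_t_test(a + 100.0, b + 100.0)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_degenerate_variance_flagged(self):
        r = welch_t_test_from_stats(1.0, 0.0, 3, 1.0, 0.0, 3)
        assert r.undefined

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestLinearTrend:
    def test_collinear_points_have_unit_r_squared(self):
        r = linear_trend([1, 2, 3, 4], [2, 4, 6, 8])
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(2.0)

    def test_published_treatment_time_trend(self):
        """Mean times vs exposure: R^2 = 0.98 (2 dp), negative slope."""
        r = linear_trend(REFERENCE_GROUPS.exposure_cm,
                         REFERENCE_GROUPS.time_mean_s)
        assert round(r.r_squared, 2) == 0.98
        assert r.slope < 0

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(size=10)
        mine = linear_trend(x, y)
        ref = scipy.stats.linregress(x, y)
        assert mine.slope == pytest.approx(ref.slope, rel=1e-12)
        assert mine.r_squared == pytest.approx(ref.rvalue**2, rel=1e-12)

    def test_constant_x_undefined(self):
        assert linear_trend([1, 1, 1], [1, 2, 3]).undefined

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linear_trend([1, 2], [1, 2])


class TestGroupSummary:
    def test_replicated_constant_has_zero_sd(self):
        import pandas as pd
        df = pd.DataFrame({"group_cm": [1.0], "volume_cm3": [5.0],
                           "time_s": [100.0]})
        out = group_summary(df)
        assert out.volume_cm3_sd.iloc[0] == 0.0

    def test_empty_table_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            group_summary(pd.DataFrame(columns=["group_cm", "volume_cm3"]))
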