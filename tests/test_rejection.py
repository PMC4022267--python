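"""Rejection tests: empirical p-values, 2D density test, LHR, diagnostics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bootgof as bg
from bootgof.rejection import (CollapsedCloudWarning, SmallCloudWarning,
                               cloud_geometry_diagnostic, combine_simplistic,
                               empirical_p_1d, kde2d, p_value_2d)


class TestEmpiricalP1D:
    cloud = np.arange(1.0, 101.0)

    def test_median_right_tail(self):
        assert empirical_p_1d(self.cloud, 50.5, "right") == pytest.approx(0.5, abs=0.01)

    def test_upper_decile_right_tail(self):
        # brute force: 10 of 100 cloud values are >= 90.5
        assert empirical_p_1d(self.cloud, 90.5, "right") == pytest.approx(0.10, abs=0.01)

    def test_out_of_range_clamped(self):
        B = self.cloud.size
        assert empirical_p_1d(self.cloud, -50.0, "left") == pytest.approx(1 / (B + 1))
        assert empirical_p_1d(self.cloud, 1e6, "right") == pytest.approx(1 / (B + 1))

    def test_two_tailed_center_and_cap(self):
        assert empirical_p_1d(self.cloud, 50.5, "two") == pytest.approx(1.0, abs=0.02)
        assert empirical_p_1d(self.cloud, 99.0, "two") < 0.1

    def test_density_tail_mode_vs_tail(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=2000)
        assert empirical_p_1d(col, 0.0, "density") > 0.9
        assert empirical_p_1d(col, 5.0, "density") < 0.01

    def test_validation(self):
        with pytest.raises(ValueError):
            empirical_p_1d(np.array([]), 1.0, "right")
        with pytest.raises(ValueError):
            empirical_p_1d(self.cloud, np.nan, "right")
        with pytest.raises(ValueError):
            empirical_p_1d(self.cloud, 1.0, "sideways")

    def test_small_cloud_warns(self):
        with pytest.warns(SmallCloudWarning):
            empirical_p_1d(np.arange(10.0), 5.0, "right")

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(-200, 200))
    def test_right_tail_monotone_and_bounded(self, observed):
        p = empirical_p_1d(self.cloud, observed, "right")
        p_larger = empirical_p_1d(self.cloud, observed + 10.0, "right")
        assert 0.0 < p < 1.0
        assert p_larger <= p + 1e-12


class TestSimplisticCombinations:
    def test_four_formulas(self):
        out = combine_simplistic(0.2, 0.6)
        assert out == {"p_min": 0.2, "p_max": 0.6,
                       "p_mean": pytest.approx(0.4),
                       "p_prod": pytest.approx(0.12)}

    def test_equal_inputs(self):
        out = combine_simplistic(0.3, 0.3)
        assert out["p_min"] == out["p_max"] == out["p_mean"] == 0.3
        assert out["p_prod"] == pytest.approx(0.09)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            combine_simplistic(1.2, 0.5)


class TestKde2d:
    def test_mass_normalized_and_quadrants(self, gauss_cloud_10k):
        pts, grid, ev = gauss_cloud_10k
        assert grid.mass.sum() == pytest.approx(1.0, abs=1e-9)
        # mass of each half-plane of an isotropic normal is 1/2
        left = grid.mass[grid.grid_x < 0, :].sum()
        assert left == pytest.approx(0.5, abs=0.02)

    def test_collapsed_column_degrades_to_1d(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([np.zeros(500), rng.normal(size=500)])
        with pytest.warns(CollapsedCloudWarning):
            grid, ev = kde2d(pts)
        assert grid.collapsed_axis == 0
        assert grid.grid_y is None
        assert grid.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_collinear_columns_degrade(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=400)
        with pytest.warns(CollapsedCloudWarning):
            grid, _ = kde2d(np.column_stack([x, 2 * x + 1]))
        assert grid.collapsed_axis == -1

    def test_both_columns_flat_error(self):
        with pytest.raises(ValueError, match="zero spread"):
            kde2d(np.ones((100, 2)))

    def test_explicit_bandwidths(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(500, 2))
        grid, ev = kde2d(pts, bandwidth=(0.3, 0.4))
        assert grid.bandwidths == (0.3, 0.4)
        assert grid.mass.sum() == pytest.approx(1.0, abs=1e-9)


class TestPValue2D:
    def test_mode_gives_p_near_one(self, gauss_cloud_10k):
        pts, grid, ev = gauss_cloud_10k
        assert p_value_2d(grid, ev, (0.0, 0.0)) > 0.95

    def test_far_point_gives_p_near_zero(self, gauss_cloud_10k):
        pts, grid, ev = gauss_cloud_10k
        assert p_value_2d(grid, ev, (8.0, 8.0)) < 1e-3

    def test_grid_convergence(self, chi2_cloud_10k):
        pts, obs = chi2_cloud_10k
        p128 = p_value_2d(*kde2d(pts, grid_n=128), obs)
        p256 = p_value_2d(*kde2d(pts, grid_n=256), obs)
        assert abs(p128 - p256) < 0.005

    def test_collapsed_cloud_p_value_matches_1d_density(self):
        rng = np.random.default_rng(4)
        live = rng.normal(size=3000)
        pts = np.column_stack([np.zeros(3000), live])
        with pytest.warns(CollapsedCloudWarning):
            grid, ev = kde2d(pts)
        p = p_value_2d(grid, ev, (0.0, 0.0))
        assert p == pytest.approx(empirical_p_1d(live, 0.0, "density"),
                                  abs=0.03)


class TestPipelines:
    @pytest.fixture()
    def reg(self):
        return bg.builtin_models()

    def test_chi2_test_result_contract(self, reg, static_fixture_dataset):
        res = bg.test_chi2(reg["MS1"], static_fixture_dataset, B=200, seed=0)
        assert 0.0 <= res.p_value <= 1.0
        assert res.tail == "right"
        assert res.rejected == (res.p_value < res.alpha)
        assert res.cloud_ref["B"] == 200

    def test_dw_test_left_tailed(self, reg, static_fixture_dataset):
        res = bg.test_dw(reg["MS1"], static_fixture_dataset, B=200, seed=0)
        assert res.tail == "left"
        assert 0.0 <= res.observed_stats["dw"] <= 4.0

    def test_dw_of_flex_fit_degenerate(self, reg, static_fixture_dataset):
        with pytest.raises(bg.DegenerateFitError):
            bg.test_dw(reg["FLEX"], static_fixture_dataset, B=100, seed=0)

    def test_2d_chi2_dw(self, reg, static_fixture_dataset):
        res = bg.test_2d(reg["MS1"], static_fixture_dataset, "dw", B=200,
                         seed=0, grid_n=64)
        assert res.test_name == "2d_chi2_dw"
        assert res.tail == "density"
        assert 0.0 <= res.p_value <= 1.0

    def test_2d_competing_returns_both_h0(self, reg, static_fixture_dataset):
        results = bg.test_2d(reg["MS1"], static_fixture_dataset, reg["MS2"],
                             B=150, seed=0, grid_n=64, competing=True)
        assert [r.meta["h0_model"] for r in results] == ["MS1", "MS2"]
        for r in results:
            assert 0.0 <= r.p_value <= 1.0

    def test_2d_with_flex_help_collapses(self, reg, static_fixture_dataset):
        res = bg.test_2d(reg["MS1"], static_fixture_dataset, reg["FLEX"],
                         B=150, seed=0, grid_n=64)
        assert res.meta.get("collapsed") is True
        assert res.warnings

    def test_lhr_flex_equals_two_tailed_chi2(self, reg,
                                             static_fixture_dataset):
        # with a zero-cost help model the LHR cloud IS the chi2 cloud
        lhr = bg.test_lhr(reg["MS1"], reg["FLEX"], static_fixture_dataset,
                          B=300, seed=1)
        chi = bg.test_chi2(reg["MS1"], static_fixture_dataset, B=300, seed=1,
                           tail="two")
        assert lhr.p_value == pytest.approx(chi.p_value, abs=1e-12)
        assert lhr.meta.get("collapsed") is True

    def test_lhr_h0_model_selection(self, reg, static_fixture_dataset):
        res = bg.test_lhr(reg["MS1"], reg["MS2"], static_fixture_dataset,
                          h0_model="model2", B=150, seed=2)
        assert res.meta["h0_model"] == "MS2"
        with pytest.raises(ValueError):
            bg.test_lhr(reg["MS1"], reg["MS2"], static_fixture_dataset,
                        h0_model="model3", B=50, seed=0)


class TestCloudGeometry:
    def test_isotropic_cloud_uncorrelated(self):
        rng = np.random.default_rng(6)
        diag = cloud_geometry_diagnostic(rng.normal(size=(10_000, 2)))
        assert abs(diag["correlation"]) < 0.05
        assert not diag["collapsed"]

    def test_perfectly_correlated_cloud(self):
        x = np.random.default_rng(7).normal(size=2000)
        diag = cloud_geometry_diagnostic(np.column_stack([x, x + 5.0]))
        assert diag["correlation"] == pytest.approx(1.0, abs=1e-9)
        assert abs(diag["principal_angle_deg"]) == pytest.approx(45.0, abs=0.5)

    def test_flex_help_cloud_collapse_flag(self):
        rng = np.random.default_rng(8)
        pts = np.column_stack([rng.normal(size=300) ** 2, np.zeros(300)])
        diag = cloud_geometry_diagnostic(pts)
        assert diag["collapsed"]
        assert diag["collapsed_axis"] == 1
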