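"""Model core: simulation, exact ODE solutions, chi-square fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import bootgof as bg
from bootgof.defaults import dynamic_design, static_design
from bootgof.models import FrozenModel, ScalarODEModel


@pytest.fixture()
def registry():
    return bg.builtin_models()


class TestSimulate:
    @pytest.mark.parametrize("model_id, theta, coords, expected", [
        ("MS1", (2.0, 1.0), [0.0, 1.0, 2.0], [1.0, 3.0, 5.0]),
        ("MS2", (1.0, 0.0), [0.0, 1.0, 2.0], [1.0, np.e, np.e ** 2]),
    ])
    def test_static_formulas(self, registry, model_id, theta, coords, expected):
        out = bg.simulate(registry[model_id], theta, bg.Design.single(coords))
        np.testing.assert_allclose(out[0], expected, rtol=1e-12)

    def test_md1_closed_form_value(self, registry):
        # x1(t) = 10 exp(-theta t): at t = ln(4)/theta the state is 10/4
        d = bg.Design.single([0.0, np.log(4) / 0.5, 10.0])
        out = bg.simulate(registry["MD1"], (0.5,), d)[0]
        np.testing.assert_allclose(out[:2], [10.0, 2.5], rtol=1e-12)

    def test_md2_initial_value(self, registry):
        d = bg.Design.single([0.0, 1.0, 2.0])
        for theta in (0.1, 3.0, 40.0):
            assert bg.simulate(registry["MD2"], (theta,), d)[0][0] == pytest.approx(10.0, abs=1e-9)

    def test_theta_outside_bounds_rejected(self, registry):
        with pytest.raises(ValueError, match="bounds"):
            bg.simulate(registry["MD1"], (-1.0,), dynamic_design())

    def test_wrong_theta_length(self, registry):
        with pytest.raises(ValueError, match="parameters"):
            registry["MS1"].predict((1.0,), static_design())


class TestExactOdeSolutions:
    @pytest.mark.parametrize("theta", [0.01, 0.1, 0.7, 2.0, 5.0])
    def test_md1_matches_numeric_integration(self, registry, theta):
        d = bg.Design.single(np.linspace(0, 10, 21))
        exact = registry["MD1"].predict((theta,), d)[0]
        ode = registry["MD1"].predict_ode((theta,), d)[0]
        # relative agreement where the state is resolvable above the
        # integrator's absolute tolerance, absolute agreement below
        big = exact > 1e-4
        assert np.max(np.abs(exact - ode)[big] / exact[big]) < 1e-6
        assert np.max(np.abs(exact - ode)[~big], initial=0.0) < 1e-8

    @pytest.mark.parametrize("theta", [0.1, 1.0, 5.0, 20.0])
    def test_md2_matches_numeric_integration(self, registry, theta):
        d = dynamic_design()
        exact = registry["MD2"].predict((theta,), d)[0]
        ode = registry["MD2"].predict_ode((theta,), d)[0]
        assert np.max(np.abs(exact - ode)) < 1e-5

    def test_md2_satisfies_implicit_form(self, registry):
        # x + 0.01 ln x = 10 + 0.01 ln 10 - theta t, root-solved independently
        theta, t = 2.0, np.linspace(0.1, 3.0, 8)
        exact = registry["MD2"].predict((theta,), bg.Design.single(t))[0]
        for tj, xj in zip(t, exact):
            c = 10 + 0.01 * np.log(10) - theta * tj
            root = brentq(lambda x: x + 0.01 * np.log(x) - c, 1e-250, 10.5,
                          xtol=1e-15)
            assert xj == pytest.approx(root, rel=1e-8, abs=1e-10)


class TestFitting:
    def test_linear_fit_exact_recovery(self, registry, noise_free_static):
        res = registry["MS1"].fit(noise_free_static)
        np.testing.assert_allclose(res.theta_hat, [4.0, 5.0], rtol=1e-12)
        assert res.chi2 == pytest.approx(0.0, abs=1e-18)
        assert res.converged

    @pytest.mark.parametrize("model_id, theta", [("MD1", 0.7), ("MD2", 0.8)])
    def test_ode_fit_recovers_generating_value(self, registry, model_id, theta):
        d = dynamic_design()
        model = registry[model_id]
        clean = bg.simulate(model, (theta,), d)
        sigma = tuple(np.full(c.size, 0.75) for c in d.coordinates)
        res = model.fit(bg.Dataset(d, clean, sigma))
        assert abs(res.theta_hat[0] - theta) < 1e-6
        assert res.chi2 <= 1e-8

    def test_fit_chi2_consistent_with_statistic(self, registry,
                                                static_fixture_dataset):
        res = registry["MS2"].fit(static_fixture_dataset)
        pred = registry["MS2"].predict(res.theta_hat,
                                       static_fixture_dataset.design)
        assert res.chi2 == pytest.approx(
            bg.chi2_statistic(static_fixture_dataset, pred), rel=1e-12)

    def test_sigma_scaling_invariance(self, registry, static_fixture_dataset):
        # multiplying all sigma by c leaves theta unchanged, divides chi2 by c^2
        ds = static_fixture_dataset
        res1 = registry["MS1"].fit(ds)
        scaled = bg.Dataset(ds.design, ds.values,
                            tuple(2.0 * s for s in ds.sigma))
        res2 = registry["MS1"].fit(scaled)
        np.testing.assert_allclose(res1.theta_hat, res2.theta_hat, rtol=1e-12)
        assert res2.chi2 == pytest.approx(res1.chi2 / 4.0, rel=1e-12)

    def test_flex_interpolates_any_dataset(self, registry,
                                           static_fixture_dataset):
        res = registry["FLEX"].fit(static_fixture_dataset)
        assert res.chi2 == 0.0
        for r in res.residuals:
            np.testing.assert_array_equal(r, 0.0)

    def test_const_is_weighted_mean(self, registry, static_fixture_dataset):
        res = registry["CONST"].fit(static_fixture_dataset)
        # constant sigma -> plain mean per signal
        assert res.theta_hat[0] == pytest.approx(
            float(np.mean(static_fixture_dataset.values[0])), rel=1e-12)

    def test_fit_many_matches_single_fits(self, registry):
        d = dynamic_design()
        model = registry["MD2"]
        rng = np.random.default_rng(9)
        clean = np.concatenate(bg.simulate(model, (5.0,), d))
        Y = clean + rng.normal(0, 0.75, size=(20, 11))
        sigma = (np.full(11, 0.75),)
        _, pred, conv = model.fit_many(d, sigma, Y)
        assert conv.all()
        for i in range(20):
            single = model.fit(bg.Dataset(d, (Y[i],), sigma))
            chi_vec = float(np.sum(((Y[i] - pred[i]) / 0.75) ** 2))
            assert chi_vec == pytest.approx(single.chi2, rel=1e-6, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-50, 50), min_size=11, max_size=11))
    def test_linear_fit_idempotent(self, values):
        ms1 = bg.builtin_models()["MS1"]
        d = static_design()
        sigma = (np.full(11, 0.5),)
        first = ms1.fit(bg.Dataset(d, (np.array(values),), sigma))
        refit = ms1.fit(bg.Dataset(d, first.predicted, sigma))
        np.testing.assert_allclose(refit.theta_hat, first.theta_hat,
                                   rtol=1e-9, atol=1e-9)
        assert refit.chi2 < 1e-16


class TestRegistry:
    def test_builtin_ids(self, registry):
        assert set(registry) == {"MS1", "MS2", "MD1", "MD2", "CONST", "FLEX"}
        assert registry["MD1"].n_params == 1
        assert isinstance(registry["MD1"], ScalarODEModel)
        assert registry["MD1"].X0 == 10.0

    def test_unknown_model_lists_registry(self):
        with pytest.raises(bg.UnknownModelError, match="MS1"):
            bg.get_model("nope")

    def test_frozen_model_has_no_free_params(self, registry,
                                             static_fixture_dataset):
        frozen = FrozenModel(registry["MS1"], (4.0, 5.0))
        assert frozen.n_params == 0
        res = frozen.fit(static_fixture_dataset)
        pred = registry["MS1"].predict((4.0, 5.0),
                                       static_fixture_dataset.design)
        assert res.chi2 == pytest.approx(
            bg.chi2_statistic(static_fixture_dataset, pred), rel=1e-12)
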