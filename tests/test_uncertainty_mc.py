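"""Analytic error propagation and the Monte Carlo uncertainty machinery."""

import numpy as np
import pytest

from trioxy.steady_budget import BudgetInputs, invert_for_cap_a, solve_f_land
from trioxy.uncertainty_mc import (BUDGET_STANDARD_ERRORS, MCConfig,
                                   budget_f_land_function, budget_parameters,
                                   propagate_f_land_se, propagate_se,
                                   propagate_tau_se, run_monte_carlo,
                                   single_measurement_error)


class TestPropagateSE:
    def test_three_four_five(self):
        res = propagate_se(lambda p: p["a"] + p["b"],
                           {"a": 0.0, "b": 0.0}, {"a": 3.0, "b": 4.0})
        assert res.se == pytest.approx(5.0, rel=1e-6)

    def test_zero_uncertainties_give_zero(self):
        res = propagate_se(lambda p: p["a"] ** 2 + p["b"],
                           {"a": 2.0, "b": 1.0}, {"a": 0.0, "b": 0.0})
        assert res.se == 0.0

    def test_agrees_with_independent_rss(self):
        # independent finite-difference root-sum-square for a nonlinear map
        def f(p):
            return p["x"] * np.exp(p["y"]) + p["z"] ** 2

        inputs = {"x": 2.0, "y": 0.5, "z": 3.0}
        errors = {"x": 0.1, "y": 0.02, "z": 0.05}
        res = propagate_se(f, inputs, errors)
        h = 1e-7
        rss = 0.0
        for k, s in errors.items():
            hi, lo = dict(inputs), dict(inputs)
            hi[k] += h
            lo[k] -= h
            rss += (((f(hi) - f(lo)) / (2 * h)) * s) ** 2
        assert res.se == pytest.approx(np.sqrt(rss), rel=1e-4)

    def test_mc_matches_analytic_for_small_normal_errors(self):
        def f(p):
            return 2 * p["a"] + p["b"] ** 2

        res = propagate_se(f, {"a": 1.0, "b": 3.0}, {"a": 0.01, "b": 0.02})
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 0.01, 10_000)
        b = rng.normal(3.0, 0.02, 10_000)
        mc_sd = np.std(2 * a + b ** 2, ddof=1)
        assert mc_sd == pytest.approx(res.se, rel=0.10)

    def test_unknown_input_rejected(self):
        with pytest.raises(KeyError):
            propagate_se(lambda p: p["a"], {"a": 1.0}, {"zzz": 1.0})

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            propagate_se(lambda p: p["a"], {"a": 1.0}, {"a": -1.0})


class TestBudgetPropagation:
    def test_f_land_se_scale_and_dominant_terms(self, default_inputs):
        res = propagate_f_land_se(default_inputs)
        assert res.value == pytest.approx(solve_f_land(default_inputs).f_land, rel=1e-6)
        # the printed +/-70 is the reference scale for this standard error
        assert 40.0 < res.se < 90.0
        top2 = set(res.contributions.index[:2])
        assert top2 == {"land_water_shift", "strat_isoflux"}
        assert res.contributions["share"].sum() == pytest.approx(1.0)

    def test_tau_se_matches_printed_band(self, default_inputs):
        res = propagate_tau_se(default_inputs)
        assert round(res.value, 1) == 1.9
        assert 0.15 < res.se < 0.45   # printed tau uncertainty is 0.3

    def test_single_measurement_inflates_error(self, default_inputs):
        se = propagate_f_land_se(default_inputs).se
        sd = single_measurement_error(default_inputs)
        assert sd.semantics == "standard_deviation"
        assert sd.se > 2.0 * se

    def test_sd_equal_se_is_identical(self, default_inputs):
        res1 = propagate_f_land_se(default_inputs)
        res2 = single_measurement_error(default_inputs, sds=BUDGET_STANDARD_ERRORS)
        assert res2.se == pytest.approx(res1.se, rel=1e-12)

    def test_doubling_all_sigmas_doubles_se(self, default_inputs):
        res1 = propagate_f_land_se(default_inputs)
        doubled = {k: 2 * v for k, v in BUDGET_STANDARD_ERRORS.items()}
        res2 = propagate_f_land_se(default_inputs, errors=doubled)
        assert res2.se == pytest.approx(2 * res1.se, rel=1e-9)

    def test_parameter_function_matches_solver(self, default_inputs):
        f = budget_f_land_function(default_inputs)
        params = budget_parameters(default_inputs)
        assert f(params) == pytest.approx(solve_f_land(default_inputs).f_land, rel=1e-12)


class TestMonteCarlo:
    def test_seed_determinism(self):
        cfg = MCConfig(n_draws=5000, seed=123)
        r1 = run_monte_carlo(cfg, keep_draws=True)
        r2 = run_monte_carlo(cfg, keep_draws=True)
        assert r1.summary.equals(r2.summary)
        assert r1.draws.equals(r2.draws)

    def test_different_seeds_differ(self):
        r1 = run_monte_carlo(MCConfig(n_draws=5000, seed=1))
        r2 = run_monte_carlo(MCConfig(n_draws=5000, seed=2))
        assert not r1.summary.equals(r2.summary)

    def test_degenerate_distributions_collapse_to_scenario(self):
        res = run_monte_carlo(MCConfig(n_draws=100, seed=0),
                              f_land_mean=345.0, f_land_se=0.0,
                              kappa_range=(1.33, 1.33), theta_range=(0.78, 0.78))
        assert res.mean("gpp") == pytest.approx(127.1, abs=0.1)
        assert res.mean("f_s") == pytest.approx(117.1, abs=0.1)
        assert res.sd("gpp") == pytest.approx(0.0, abs=1e-9)

    def test_joint_summary_within_published_bands(self):
        res = run_monte_carlo(MCConfig(n_draws=125_000, seed=7))
        assert 90.0 < res.mean("gpp") < 150.0      # 120 +/- 30
        assert 80.0 < res.mean("f_s") < 140.0      # 110 +/- 30
        assert res.converged

    def test_mc_sd_of_f_land_matches_analytic_propagation(self, default_inputs):
        # purely normal, small-error configuration: coupled-mode MC spread
        # vs first-order propagation
        small = {k: v / 10 for k, v in BUDGET_STANDARD_ERRORS.items()}
        analytic = propagate_f_land_se(default_inputs, errors=small)
        from trioxy.uncertainty_mc import solve_f_land_vectorized  # noqa: F401
        rng = np.random.default_rng(5)
        f = budget_f_land_function(default_inputs)
        params = budget_parameters(default_inputs)
        draws = []
        n = 10_000
        samples = {k: rng.normal(params[k], small[k], n) for k in small}
        for i in range(n):
            p = dict(params)
            p.update({k: samples[k][i] for k in small})
            draws.append(f(p))
        assert np.std(draws, ddof=1) == pytest.approx(analytic.se, rel=0.10)

    def test_rejection_counting(self):
        # an F_land distribution straddling zero produces rejections
        res = run_monte_carlo(MCConfig(n_draws=20_000, seed=3),
                              f_land_mean=50.0, f_land_se=100.0,
                              sc=None)
        assert res.n_rejected > 0
        assert res.n_draws + res.n_rejected == 20_000

    def test_factorial_mode_agrees_with_joint(self):
        joint = run_monte_carlo(MCConfig(n_draws=200_000, seed=11))
        fact = run_monte_carlo(MCConfig(mode="factorial", seed=11, n_per_variable=500))
        assert fact.mean("gpp") == pytest.approx(joint.mean("gpp"), rel=0.05)
        assert fact.sd("gpp") == pytest.approx(joint.sd("gpp"), rel=0.10)

    def test_coupled_mode_reasonable(self, default_inputs):
        res = run_monte_carlo(MCConfig(n_draws=30_000, seed=9, mode="coupled"),
                              inputs=default_inputs)
        assert res.mean("f_land") == pytest.approx(
            solve_f_land(default_inputs).f_land, rel=0.10)

    def test_parameter_recovery_small_noise(self, default_inputs):
        # forward-simulate observed Delta-17O from a known flux, invert each
        # draw; the mean recovers the truth within 2 MC standard errors
        # (small-noise regime, where first-order unbiasedness holds)
        from dataclasses import replace
        f_true = 300.0
        _, cap_log = invert_for_cap_a(default_inputs, f_true)
        rng = np.random.default_rng(11)
        caps = rng.normal(cap_log, 0.0005, 2000)
        recovered = np.array([
            solve_f_land(replace(default_inputs, cap_a_log=float(c))).f_land
            for c in caps])
        mc_se = recovered.std(ddof=1) / np.sqrt(recovered.size)
        assert abs(recovered.mean() - f_true) <= 2.0 * mc_se

    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            MCConfig(n_draws=0)
        with pytest.raises(ValueError):
            MCConfig(mode="exhaustive")
        with pytest.raises(ValueError):
            run_monte_carlo(MCConfig(n_draws=10), kappa_range=(2.0, 1.0))
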