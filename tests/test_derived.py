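"""Derived thinning line, effect sizes, propagation, projections, trajectories."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from selfthin.derived import (Scenario, capacity_multiplier, carbon_impact,
                              density_at_matched_d, intercept_effect, project_capacity,
                              propagate, simulate_trajectory, stl_from_params, stl_results)

EQ3 = {"beta0": -29.61, "beta1": 2.95, "beta2": 2.40, "beta5": 0.22, "theta": 9.42}


class TestClosedForms:
    @pytest.mark.parametrize("b0, b1, b2, intercept, slope", [
        (-29.61, 2.95, 2.40, 12.55, -1.65),   # composite-model coefficients
        (-29.38, 2.92, 2.38, 12.55, -1.65),   # space/time-model coefficients
        (0.0, 0.0, 1.0, 0.0, -1.0),           # log terms cancel exactly
    ])
    def test_stl_from_params(self, b0, b1, b2, intercept, slope):
        a, s = stl_from_params(b0, b1, b2)
        assert round(float(a), 2) == intercept
        assert round(float(s), 2) == slope

    def test_stl_domain_errors(self):
        with pytest.raises(ValueError):
            stl_from_params(-29.0, 2.9, -1.0)
        with pytest.raises(ValueError):
            stl_from_params(-29.0, -1.5, 2.4)

    @pytest.mark.parametrize("bk, b2, expected", [
        (0.22, 2.40, -0.0917),
        (0.28, 2.38, -0.1176),
        (0.0, 2.4, 0.0),
    ])
    def test_intercept_effect(self, bk, b2, expected):
        assert float(intercept_effect(bk, b2)) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("eff, dt, expected", [
        (-0.09, 1.0, 0.9139),
        (-0.09, 3.0, 0.7634),
        (-0.42, 0.0, 1.0),
    ])
    def test_capacity_multiplier(self, eff, dt, expected):
        assert float(capacity_multiplier(eff, dt)) == pytest.approx(expected, abs=5e-5)

    @given(hst.floats(min_value=-0.5, max_value=0.5),
           hst.floats(min_value=0, max_value=5), hst.floats(min_value=0, max_value=5))
    def test_multiplier_exponential_additivity(self, eff, a, b):
        lhs = capacity_multiplier(eff, a + b)
        rhs = capacity_multiplier(eff, a) * capacity_multiplier(eff, b)
        assert float(lhs) == pytest.approx(float(rhs), rel=1e-9)

    def test_line_scale_consistency_with_mortality(self):
        # along the derived line, expected per-tree mortality per cm of QMD
        # growth equals -slope/D at every size
        a, s = stl_from_params(EQ3["beta0"], EQ3["beta1"], EQ3["beta2"])
        for d in np.linspace(10, 120, 20):
            log_n = a + s * math.log(d)
            rate = math.exp(EQ3["beta0"] + EQ3["beta1"] * math.log(d)
                            + EQ3["beta2"] * log_n)
            assert rate == pytest.approx(-s / d, rel=1e-9)


class TestPropagate:
    def test_identity_reproduces_summaries(self):
        rng = np.random.default_rng(0)
        draws = pd.DataFrame({"x": rng.normal(2.0, 0.5, 4000)})
        out = propagate(draws, lambda p: p["x"])
        assert out["mean"] == pytest.approx(draws["x"].mean(), rel=1e-12)
        assert out["lower"] == pytest.approx(draws["x"].quantile(0.025), rel=1e-9)

    def test_lognormal_closed_form(self):
        rng = np.random.default_rng(1)
        draws = pd.DataFrame({"x": rng.normal(0.0, 1.0, 40000)})
        out = propagate(draws, lambda p: math.exp(p["x"]))
        assert out["mean"] == pytest.approx(math.exp(0.5), rel=0.05)
        assert out["lower"] == pytest.approx(math.exp(-1.96), rel=0.08)
        assert out["upper"] == pytest.approx(math.exp(1.96), rel=0.08)

    def test_quantiles_match_independent_pass(self):
        rng = np.random.default_rng(2)
        draws = pd.DataFrame({"b": rng.normal(2.4, 0.1, 500)})
        out = propagate(draws, lambda p: 1.0 / p["b"])
        brute = np.sort(1.0 / draws["b"].to_numpy())
        assert out["lower"] == np.quantile(brute, 0.025)
        assert out["upper"] == np.quantile(brute, 0.975)

    def test_fails_loudly_on_undefined_draws(self):
        draws = pd.DataFrame({"beta2": np.concatenate([np.full(150, 2.4), [-1.0]])})
        with pytest.raises(ValueError, match="undefined"):
            propagate(draws, lambda p: math.log(p["beta2"]))

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError):
            propagate(pd.DataFrame({"x": np.ones(50)}), lambda p: p["x"])

    def test_nonlinear_interval_differs_from_plug_in(self, composite_fit):
        _, fit = composite_fit
        line = stl_results(fit)
        # point transform of the estimate equals the closed form...
        a, s = stl_from_params(fit.params["beta0"], fit.params["beta1"], fit.params["beta2"])
        assert line.intercept == pytest.approx(float(a), rel=1e-12)
        # ...but the interval comes from the draws, not the plug-in point
        assert line.intercept_ci[0] < line.intercept < line.intercept_ci[1]
        assert line.slope < 0


class TestProjectionAndCarbon:
    def test_percent_change_consistency(self):
        proj = project_capacity(-0.0917, 3.0)
        assert proj.capacity_multiplier == pytest.approx(math.exp(-0.2751), abs=1e-4)
        assert proj.percent_change == pytest.approx(100 * (proj.capacity_multiplier - 1))

    def test_published_carbon_arithmetic(self):
        impact = carbon_impact(0.24, 450.0, 1_000_000.0)
        assert impact.carbon_loss == pytest.approx(1.08e8)
        assert impact.equivalent_area == pytest.approx(240_000.0)
        # one person driving 10,000 km/yr for 75 yr at 146 g C/km
        assert impact.car_equivalent_people() == pytest.approx(9.863e5, rel=1e-3)

    def test_zero_drop_rejected(self):
        with pytest.raises(ValueError):
            carbon_impact(0.0, 450.0, 1e6)

    def test_invariant_loss_equals_fraction_times_area(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            f, c, a = rng.uniform(0.01, 0.9), rng.uniform(50, 900), rng.uniform(1e3, 1e7)
            imp = carbon_impact(f, c, a)
            assert imp.carbon_loss == pytest.approx(f * c * a, rel=1e-12)
            assert imp.equivalent_area == pytest.approx(f * a, rel=1e-12)


class TestTrajectories:
    def test_zero_shift_equals_baseline(self):
        base = simulate_trajectory(EQ3, Scenario("baseline"), t_max=80)
        zero = simulate_trajectory(EQ3, Scenario("transient", delta_t=0.0, start=20, end=30),
                                   t_max=80)
        assert np.allclose(base[["D", "N"]].values, zero[["D", "N"]].values)

    def test_stochastic_mode_reproducible(self):
        a = simulate_trajectory(EQ3, mode="stochastic", seed=4, t_max=60)
        b = simulate_trajectory(EQ3, mode="stochastic", seed=4, t_max=60)
        assert a.equals(b)

    def test_permanent_warming_matches_capacity_multiplier(self):
        base = simulate_trajectory(EQ3, Scenario("baseline"), t_max=200)
        perm = simulate_trajectory(EQ3, Scenario("permanent", delta_t=3.0), t_max=200)
        d = min(base["D"].iloc[-1], perm["D"].iloc[-1]) * 0.98
        ratio = density_at_matched_d(perm, d) / density_at_matched_d(base, d)
        assert ratio == pytest.approx(0.7634, rel=0.05)

    def test_transient_recovers_baseline_trajectory(self):
        base = simulate_trajectory(EQ3, Scenario("baseline"), t_max=200)
        tr = simulate_trajectory(EQ3, Scenario("transient", delta_t=3.0, start=40, end=50),
                                 t_max=200)
        d = min(base["D"].iloc[-1], tr["D"].iloc[-1]) * 0.98
        gap = abs(math.log(density_at_matched_d(tr, d)) - math.log(density_at_matched_d(base, d)))
        assert gap < 0.02

    def test_collapse_flagged(self):
        hot = dict(EQ3, beta0=-20.0)  # absurd mortality level
        tr = simulate_trajectory(hot, t_max=300)
        assert tr.attrs["collapsed"]
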