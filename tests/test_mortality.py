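"""NB mortality GLMM: pmf, linear predictor, fitting, prediction."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import selfthin as st
from selfthin.mortality import MortalityModel, linear_predictor, nb_logpmf

EQ3_TRUTH = {"beta0": -29.61, "beta1": 2.95, "beta2": 2.40, "beta5": 0.22,
             "sigma_beta0": 0.84, "theta": 9.42}


class TestNbLogpmf:
    def test_normalizes_to_one(self):
        y = np.arange(0, 201)
        total = np.exp(nb_logpmf(y, 2.0, 5.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_poisson_limit(self):
        y = np.arange(0, 21)
        ours = nb_logpmf(y, 3.0, 1e8)
        poisson = stats.poisson.logpmf(y, 3.0)
        assert np.max(np.abs(ours - poisson)) < 1e-4

    def test_moments_by_simulation(self):
        mu, theta = 4.0, 2.0
        rng = np.random.default_rng(0)
        draws = rng.negative_binomial(theta, theta / (theta + mu), size=100_000)
        target_var = mu + mu**2 / theta  # = 12
        assert draws.var() == pytest.approx(target_var, rel=0.05)
        assert draws.mean() == pytest.approx(mu, rel=0.02)

    def test_agrees_with_scipy_nbinom(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            y = int(rng.integers(0, 400))
            mu = float(rng.uniform(0.01, 200))
            theta = float(rng.uniform(0.1, 50))
            ref = stats.nbinom.logpmf(y, theta, theta / (theta + mu))
            assert nb_logpmf(y, mu, theta) == pytest.approx(ref, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_logpmf(-1, 2.0, 5.0)
        with pytest.raises(ValueError):
            nb_logpmf(2, -1.0, 5.0)
        with pytest.raises(ValueError):
            nb_logpmf(2, 1.0, 0.0)


class TestLinearPredictor:
    def test_offsets_enter_with_unit_coefficient(self):
        p = dict(EQ3_TRUTH)
        base = linear_predictor(p, 50, 300, 1.0, 78)
        doubled = linear_predictor(p, 50, 300, 2.0, 78)
        assert np.exp(doubled) == pytest.approx(2 * np.exp(base), rel=1e-12)

    def test_reference_point_evaluation(self):
        # mu at D=50, N=300/ha, 0.26 ha (N_raw=78), dD=1, MAT at centre
        eta = linear_predictor(EQ3_TRUTH, 50.0, 300.0, 1.0, 78.0, "eq_composite", mat_ij_c=0.0)
        expected = (-29.61 + 2.95 * math.log(50) + 2.40 * math.log(300)
                    + math.log(1.0) + math.log(78.0))
        assert float(eta) == pytest.approx(expected, rel=1e-12)
        assert math.exp(eta) == pytest.approx(0.97, abs=0.02)

    def test_variant_identity_when_effects_equal(self):
        p = dict(EQ3_TRUTH, beta3=0.22, beta4=0.22)
        eta2 = linear_predictor(p, 40, 500, 1.2, 100, "eq_space_time",
                                mat_longterm_c=0.7, mat_anomaly=0.0)
        eta3 = linear_predictor(p, 40, 500, 1.2, 100, "eq_composite", mat_ij_c=0.7)
        assert float(eta2) == pytest.approx(float(eta3), rel=1e-12)

    def test_rejects_nonpositive_growth(self):
        with pytest.raises(ValueError):
            linear_predictor(EQ3_TRUTH, 50, 300, 0.0, 78)


class TestFit:
    def test_composite_recovery_on_reference_truth(self, composite_fit):
        ds, fit = composite_fit
        ci = fit.conf_int()
        for name in ("beta0", "beta1", "beta2", "beta5"):
            truth = EQ3_TRUTH[name]
            assert ci.loc[name, "lower"] <= truth <= ci.loc[name, "upper"], name
        assert fit.params["sigma_beta0"] == pytest.approx(0.84, abs=0.2)
        assert fit.params["theta"] == pytest.approx(9.42, rel=0.3)

    def test_null_climate_effect_covered(self):
        truth = st.TruthParams.composite(beta3=0.0, beta4=0.0, beta5=0.0)
        ds = st.gen_dataset(st.GeneratorConfig(n_plots=40, n_control=20),
                            truth=truth, seed=21, tree_level=False)
        fit = MortalityModel.from_dataframe(ds.model_frame(), variant="eq_composite",
                                            mat_center=11.0).fit(seed=0, n_draws=500)
        ci = fit.conf_int()
        assert ci.loc["beta5", "lower"] <= 0.0 <= ci.loc["beta5", "upper"]

    def test_space_time_effects_similar_when_generated_equal(self, composite_fit):
        # generator used beta3 = beta4; the decomposed fit should agree
        ds, _ = composite_fit
        fit = MortalityModel.from_dataframe(ds.model_frame(), variant="eq_space_time",
                                            mat_center=11.0).fit(seed=0, n_draws=1000)
        d = fit.draws
        diff = d["beta3"] - d["beta4"]
        assert abs(diff.mean()) < 2 * diff.std()

    def test_zero_mortality_rejected(self):
        df = pd.DataFrame({
            "delta_N": [0, 0, 0, 0], "D_start": [20, 25, 20, 25],
            "N_start": [800, 700, 900, 650], "delta_D": [1, 1, 1, 1],
            "N_raw_start": [80, 70, 90, 65], "plot_id": ["a", "a", "b", "b"],
            "mat_longterm": [11, 11, 12, 12], "mat_ij": [11, 11, 12, 12],
        })
        with pytest.raises(ValueError, match="unidentifiable"):
            MortalityModel.from_dataframe(df)

    def test_single_plot_rejected(self):
        df = pd.DataFrame({
            "delta_N": [1, 2], "D_start": [20, 25], "N_start": [800, 700],
            "delta_D": [1, 1], "N_raw_start": [80, 70], "plot_id": ["a", "a"],
            "mat_longterm": [11, 11], "mat_ij": [11, 11],
        })
        with pytest.raises(ValueError, match="two plots"):
            MortalityModel.from_dataframe(df)


class TestPredict:
    def test_rate_is_area_free(self, composite_fit):
        _, fit = composite_fit
        # same per-ha structure on plots of different size: mu scales with
        # N_raw, so the rate mu/N_raw is unchanged
        a = fit.predict(30.0, 500.0, 1.0, 50.0, mat_ij=11.0)
        b = fit.predict(30.0, 500.0, 1.0, 200.0, mat_ij=11.0)
        assert a["rate"].iloc[0] == pytest.approx(b["rate"].iloc[0], rel=1e-12)
        assert b["mu"].iloc[0] == pytest.approx(4 * a["mu"].iloc[0], rel=1e-12)

    def test_one_degree_multiplies_by_exp_beta5(self, composite_fit):
        _, fit = composite_fit
        a = fit.predict(30.0, 500.0, 1.0, 50.0, mat_ij=11.0)
        b = fit.predict(30.0, 500.0, 1.0, 50.0, mat_ij=12.0)
        ratio = b["mu"].iloc[0] / a["mu"].iloc[0]
        assert ratio == pytest.approx(np.exp(fit.params["beta5"]), rel=1e-9)

    def test_published_effect_size_implies_24_6_percent(self):
        # with beta5 = 0.22, +1 C multiplies mortality rate by e^0.22 = 1.246
        assert 100 * (math.exp(0.22) - 1) == pytest.approx(24.6, abs=0.05)


class TestAgainstGlmmTMB:
    def test_marginal_ml_matches_independent_laplace_fit(self):
        """Cross-validate the adaptive-quadrature fit against R glmmTMB."""
        truth = st.TruthParams.composite()
        ds = st.gen_dataset(st.GeneratorConfig(n_plots=15, n_control=8),
                            truth=truth, seed=5, tree_level=False)
        per = ds.model_frame()
        per["mat_ij_c"] = per["mat_ij"] - 11.0
        fit = MortalityModel.from_dataframe(per, variant="eq_composite",
                                            mat_center=11.0).fit(seed=0, n_draws=200)
        import tempfile
        with tempfile.TemporaryDirectory() as td:
            per.assign(log_d=np.log(per.D_start), log_n=np.log(per.N_start),
                       off=np.log(per.delta_D) + np.log(per.N_raw_start)
                       ).to_csv(f"{td}/d.csv", index=False)
            rcode = textwrap.dedent(f"""
                suppressMessages(library(glmmTMB))
                d <- read.csv("{td}/d.csv")
                m <- glmmTMB(delta_N ~ log_d + log_n + mat_ij_c + (1|plot_id) + offset(off),
                             family=nbinom2, data=d)
                fe <- fixef(m)$cond
                cat(fe, sqrt(VarCorr(m)$cond$plot_id[1,1]), sigma(m), "\\n")
            """)
            out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                                 text=True, timeout=300)
        assert out.returncode == 0, out.stderr[-500:]
        ref = [float(v) for v in out.stdout.split()]
        ours = [fit.params[k] for k in ("beta0", "beta1", "beta2", "beta5",
                                        "sigma_beta0", "theta")]
        assert np.allclose(ours, ref, rtol=2e-2), (ours, ref)
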