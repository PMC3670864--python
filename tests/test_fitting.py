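import numpy as np
import pytest
from scipy import stats

from popreconstruct.data import ModelSpec, TelemetryData
from popreconstruct.fitting import (fisher_se, fit, joint_negloglik,
                                    standard_errors, abundance_uncertainty)
from popreconstruct.process import ParameterState


class TestJointNegloglik:
    def test_removing_telemetry_changes_by_exactly_the_telemetry_term(self, low_var_pop):
        pop, tel = low_var_pop
        data = pop.to_age_at_harvest()
        spec = ModelSpec("HT", "FE")
        params = ParameterState(0.5, 0.55)
        with_tel = joint_negloglik(params, data, tel, spec)
        without = joint_negloglik(params, data, TelemetryData(), spec)
        # telemetry component recomputed independently
        P = 1 - np.exp(-0.55 * data.effort)
        term = 0.0
        for y, n, h in zip(tel.year, tel.n_at_risk, tel.n_harvested):
            term += stats.binom.logpmf(h, n, P[data.year_index(int(y))])
        assert with_tel - without == pytest.approx(-float(term), rel=1e-9)

    def test_re_model_with_tiny_sigma_approaches_fe_plus_penalty(self, low_var_pop):
        pop, tel = low_var_pop
        data = pop.to_age_at_harvest()
        fe = joint_negloglik(ParameterState(0.5, 0.55), data, tel, ModelSpec("HT", "FE"))
        sigma = 1e-3
        re = joint_negloglik(
            ParameterState(0.5, 0.55, sigma_s=sigma, sigma_c=sigma,
                           delta=np.zeros(data.n_years), nu=np.zeros(data.n_years)),
            data, tel, ModelSpec("HT", "RE"))
        penalty = -2 * data.n_years * stats.norm.logpdf(0.0, scale=sigma)
        assert re == pytest.approx(fe + penalty, rel=1e-9)

    def test_gradient_vanishes_on_expectation_matched_data(self):
        """With counts equal to their model expectations, the truth is a
        stationary point of the joint likelihood (checked by finite
        differences on the fixed effects)."""
        from types import SimpleNamespace

        from popreconstruct._engine import TwoClassEngine

        Y = 6
        s, P = 0.5, 0.4
        N_entry = 10000.0
        # build exact expected counts under constant parameters
        A = np.empty(Y)
        A[0] = 15000.0
        for i in range(Y - 1):
            A[i + 1] = (A[i] + N_entry) * (1 - P) * s
        xJ = np.full(Y, N_entry * P)
        xA = A * P
        data = SimpleNamespace(
            n_years=Y, juvenile_harvest=xJ, adult_harvest=xA,
            effort=np.ones(Y), years=np.arange(1, Y + 1),
            total_harvest=xJ + xA,
            year_index=lambda y: int(y) - 1)
        spec = ModelSpec("HT", "FE")
        eng = TwoClassEngine(data, TelemetryData(), spec)
        c = -np.log1p(-P)

        def f(theta):
            eng.set_params(theta[0], theta[1])
            return float(eng.negloglik(np.zeros((1, 0)))[0])

        theta0 = np.array([s, c])
        g = np.empty(2)
        for i in range(2):
            h = 1e-5 * max(1.0, abs(theta0[i]))
            e = np.zeros(2); e[i] = h
            g[i] = (f(theta0 + e) - f(theta0 - e)) / (2 * h)
        scale = abs(f(theta0)) + 1.0
        np.testing.assert_allclose(g / scale, 0.0, atol=1e-5)


class TestFit:
    def test_deterministic_given_identical_inputs(self, zero_var_pop):
        pop, tel = zero_var_pop
        spec = ModelSpec("HT", "RE")
        r1 = fit(spec, pop.to_age_at_harvest(), tel, compute_uncertainty=False)
        r2 = fit(spec, pop.to_age_at_harvest(), tel, compute_uncertainty=False)
        for k in r1.params:
            assert r1.params[k] == r2.params[k]
        assert r1.loglik == r2.loglik

    def test_parameter_recovery_zero_variation(self):
        """Across replicate zero-variation populations with six telemetry
        years, the mean recovered survival and harvest rate sit within two
        Monte Carlo standard errors of the generating values."""
        from popreconstruct.simulate import (SimulationConfig,
                                             simulate_population,
                                             simulate_telemetry)
        s_hats, P_hats = [], []
        for seed in range(10, 22):
            cfg = SimulationConfig(sigma_level=0.0, telemetry_design="6yr",
                                   seed=seed)
            pop = simulate_population(cfg)
            tel = simulate_telemetry(pop)
            res = fit(ModelSpec("HT", "RE"), pop.to_age_at_harvest(), tel,
                      compute_uncertainty=False)
            s_hats.append(res.params["s_base"])
            P_hats.append(1 - np.exp(-res.params["c"] * float(np.mean(pop.effort))))
        for vals, truth in ((np.array(s_hats), 0.5), (np.array(P_hats), 0.4)):
            mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - truth) < 2 * mc_se

    def test_fe_matches_re_on_zero_variation_data(self, zero_var_pop):
        pop, tel = zero_var_pop
        re = fit(ModelSpec("HT", "RE"), pop.to_age_at_harvest(), tel,
                 compute_uncertainty=False)
        fe = fit(ModelSpec("HT", "FE"), pop.to_age_at_harvest(), tel,
                 compute_uncertainty=False)
        assert fe.params["s_base"] == pytest.approx(re.params["s_base"], abs=0.02)
        assert fe.params["c"] == pytest.approx(re.params["c"], rel=0.05)

    def test_result_contract(self, zero_var_pop):
        pop, tel = zero_var_pop
        res = fit(ModelSpec("HT", "RE"), pop.to_age_at_harvest(), tel)
        ab = abundance_uncertainty(res)
        assert (ab["lo95"] <= ab["estimate"]).all()
        assert (ab["estimate"] <= ab["hi95"]).all()
        assert (ab["estimate"] >= pop.to_age_at_harvest().total_harvest - 1e-6).all()
        se = standard_errors(res)
        assert all(v >= 0 or np.isnan(v) for v in se.values())
        assert res.aic == pytest.approx(2 * len(res.params) - 2 * res.loglik)


class TestFisherSE:
    def test_binomial_closed_form(self):
        n, x = 400, 160
        nll = lambda th: -float(stats.binom.logpmf(x, n, th[0]))
        se = fisher_se(nll, [x / n])
        p = x / n
        assert se[0] == pytest.approx(np.sqrt(p * (1 - p) / n), rel=1e-3)

    def test_information_scales_with_counts(self):
        def se_for(n, x):
            nll = lambda th: -float(stats.binom.logpmf(x, n, th[0]))
            return fisher_se(nll, [x / n])[0]
        assert se_for(800, 320) == pytest.approx(se_for(200, 80) / 2, rel=1e-3)
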