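from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2

from popreconstruct.turkey import (TurkeyModelSpec, boundary_lrt,
                                   expected_adults_next_year, fit_turkey,
                                   interval_survival, juvenile_spring_abundance,
                                   mixture_chi2_pvalue, model_selection,
                                   poult_hen_comparison, spring_abundance,
                                   turkey_harvest_prob)


class TestIntervalSurvival:
    def test_summer_scaling(self):
        assert interval_survival(0.58, weeks=22) == pytest.approx(0.58 ** (22 / 46))
        assert interval_survival(0.58, weeks=22) == pytest.approx(0.771, abs=5e-3)

    def test_certain_survival(self):
        assert interval_survival(1 - 1e-12, weeks=24) == pytest.approx(1.0)

    @given(st.floats(0.05, 0.95), st.floats(-1, 1))
    def test_summer_winter_compose_to_annual(self, s, delta):
        total = interval_survival(s, delta, 22) * interval_survival(s, delta, 24)
        from popreconstruct.process import survival
        assert total == pytest.approx(float(survival(s, delta)), rel=1e-12)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_survival(0.5, weeks=30)


class TestExpectedAdultsNextYear:
    def test_closed_lossless_population(self):
        out = expected_adults_next_year(1000, 2000, 0, 0, 0, PJ=0.0, PA=0.0,
                                        s_base=1 - 1e-12)
        assert out == pytest.approx(3000.0, rel=1e-9)

    def test_exhaustion(self):
        out = expected_adults_next_year(1000, 2000, 1000, 0, 0, PJ=0.11,
                                        PA=1.0, s_base=0.58)
        assert out == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_chain(self):
        s = 0.58
        sS, sW = s ** (22 / 46), s ** (24 / 46)
        want = ((950 * (1 - 0.11) + 2000 * (1 - 0.40)) * sS - 200) * sW
        out = expected_adults_next_year(1000, 2000, 50, 0, 200, PJ=0.11,
                                        PA=0.40, s_base=s)
        assert out == pytest.approx(want, rel=1e-12)

    def test_negative_stage_reported(self):
        with pytest.raises(ValueError, match="juvenile removals"):
            expected_adults_next_year(10, 100, 20, 0, 0, 0.1, 0.4, 0.5)
        with pytest.raises(ValueError, match="fall adult"):
            expected_adults_next_year(100, 100, 0, 0, 500, 0.1, 0.4, 0.5)


class TestMixtureChi2:
    def test_zero_statistic_convention(self):
        assert mixture_chi2_pvalue(0.0) == 1.0

    def test_five_percent_critical_value(self):
        assert mixture_chi2_pvalue(2.706) == pytest.approx(0.05, abs=2e-4)

    @given(st.floats(0.001, 30.0))
    def test_matches_mixture_cdf_oracle(self, stat):
        want = 0.5 * chi2.sf(stat, df=1)  # the chi2_0 half has no mass beyond 0
        assert mixture_chi2_pvalue(stat) == pytest.approx(want, rel=1e-12)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            mixture_chi2_pvalue(-0.1)


class TestPoultHenComparison:
    def _stub_fit(self, juv_series, years):
        eng = SimpleNamespace(xJ=juv_series, RJs=np.zeros(len(years)), years=years)
        return SimpleNamespace(extra={"engine": eng, "PJ": np.ones(len(years))})

    def test_identical_rescaled_series_gives_unit_correlation(self):
        years = np.arange(2000, 2010)
        base = np.array([3, 1, 4, 1, 5, 9, 2, 6, 5, 3], dtype=float)
        fit_stub = self._stub_fit(base, years)
        ratio = pd.Series(np.concatenate([[base[0]], base]) * 0.01,
                          index=np.arange(1999, 2010))
        # ratio in year i-1 equals (rescaled) juvenile abundance in year i
        ratio = pd.Series(base * 0.01, index=years - 1)
        assert poult_hen_comparison(fit_stub, ratio) == pytest.approx(1.0)

    def test_constant_series_undefined(self):
        years = np.arange(2000, 2008)
        fit_stub = self._stub_fit(np.arange(8.0) + 1, years)
        ratio = pd.Series(np.ones(8), index=years - 1)
        assert np.isnan(poult_hen_comparison(fit_stub, ratio))

    def test_missing_prior_year_rejected(self, turkey_fit):
        with pytest.raises(ValueError):
            poult_hen_comparison(turkey_fit, pd.Series([1.0], index=[2050]))


class TestTurkeyFit:
    def test_abundance_dominates_known_removals(self, turkey_fit, turkey_dataset):
        ab = spring_abundance(turkey_fit)
        h = turkey_dataset.harvest
        r = turkey_dataset.removals
        floor = (h.juvenile_harvest + h.adult_harvest
                 + r.spring_npr_juvenile + r.spring_npr_adult)
        assert np.all(ab.to_numpy() >= floor - 1e-6)

    def test_juvenile_series_positive_and_aligned(self, turkey_fit):
        juv = juvenile_spring_abundance(turkey_fit)
        assert juv.index[0] == 1996 and juv.index[-1] == 2010
        assert (juv > 0).all()

    def test_harvest_prob_function_matches_engine(self, turkey_fit, turkey_dataset):
        cJ = turkey_fit.params["c_juvenile"]
        f = turkey_dataset.harvest.effort
        np.testing.assert_allclose(
            turkey_harvest_prob(cJ, f, turkey_fit.eb_effects["nu_juvenile"]),
            turkey_fit.extra["PJ"], rtol=1e-10)

    def test_reproducible(self, turkey_dataset, turkey_fit):
        again = fit_turkey(turkey_dataset, compute_uncertainty=False)
        for k, v in again.params.items():
            assert v == turkey_fit.params[k]


class TestModelSelection:
    def test_ranking_and_boundary_test(self, turkey_dataset):
        cands = [
            TurkeyModelSpec(True, ("vuln_juvenile", "vuln_adult")),
            TurkeyModelSpec(True, ("vuln_juvenile", "vuln_adult", "survival")),
        ]
        table = model_selection(turkey_dataset, cands)
        assert len(table) == 2
        assert table["aic"].is_monotonic_increasing
        # AIC differences are invariant to shared additive log-lik constants
        assert np.allclose(np.diff(table["aic"]),
                           -2 * np.diff(table["loglik"]) + 2 * np.diff(table["k"]))
        full = fit_turkey(turkey_dataset, cands[1], compute_uncertainty=False)
        reduced = fit_turkey(turkey_dataset, cands[0], compute_uncertainty=False)
        out = boundary_lrt(full, reduced)
        assert out["statistic"] >= 0
        assert 0 <= out["p_value"] <= 1
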