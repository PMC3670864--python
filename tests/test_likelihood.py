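import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from popreconstruct.data import TelemetryData
from popreconstruct.likelihood import (NEG_SENTINEL, catch_effort_loglik,
                                       cohort_loglik, conditional_cell_probs,
                                       edge_cohort_loglik, re_penalty,
                                       telemetry_loglik)


class TestConditionalCellProbs:
    def test_symmetry(self):
        np.testing.assert_allclose(conditional_cell_probs([120, 120]), [0.5, 0.5])

    def test_chain_normalization(self):
        p = conditional_cell_probs([400, 120, 36])
        np.testing.assert_allclose(p, [0.7194, 0.2158, 0.0647], atol=5e-5)

    def test_single_cell(self):
        np.testing.assert_allclose(conditional_cell_probs([7.0]), [1.0])

    def test_degenerate_cohort_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            conditional_cell_probs([0.0, 0.0])

    @given(st.lists(st.floats(0.01, 1e4), min_size=1, max_size=8))
    def test_probabilities_sum_to_one(self, expected):
        assert conditional_cell_probs(expected).sum() == pytest.approx(1.0, abs=1e-12)


class TestCohortLoglik:
    def test_two_trial_enumeration(self):
        assert cohort_loglik([1, 1], [0.5, 0.5]) == pytest.approx(np.log(0.5))

    def test_binomial_pmf_case(self):
        assert cohort_loglik([2, 0], [0.5, 0.5]) == pytest.approx(np.log(0.25))

    def test_single_cell_is_zero(self):
        assert cohort_loglik([9], [1.0]) == 0.0

    @given(st.lists(st.integers(0, 12), min_size=2, max_size=4),
           st.lists(st.floats(0.05, 1.0), min_size=4, max_size=4))
    def test_matches_multinomial_oracle(self, x, w):
        w = np.array(w[:len(x)])
        p = w / w.sum()
        want = stats.multinomial.logpmf(x, n=sum(x), p=p)
        assert cohort_loglik(x, p) == pytest.approx(float(want), abs=1e-9)

    @given(st.lists(st.integers(0, 9), min_size=3, max_size=4))
    def test_equals_sequential_conditional_binomials(self, x):
        x = np.array(x, dtype=float)
        if x.sum() == 0:
            return
        p = np.array([0.5, 0.3, 0.15, 0.05][:len(x)])
        p = p / p.sum()
        total = 0.0
        rem_n, rem_p = x.sum(), 1.0
        for xi, pi in zip(x[:-1], p[:-1]):
            total += stats.binom.logpmf(xi, rem_n, pi / rem_p)
            rem_n -= xi
            rem_p -= pi
        assert cohort_loglik(x, p) == pytest.approx(float(total), abs=1e-8)

    def test_zero_probability_with_count_is_sentinel(self):
        with pytest.warns(UserWarning):
            assert cohort_loglik([1, 1], [1.0, 0.0]) <= NEG_SENTINEL


class TestEdgeCohortLoglik:
    def test_matches_binomial_pmf(self):
        want = stats.binom.logpmf(12, 30, 0.4)
        assert edge_cohort_loglik(12, 30, 0.4) == pytest.approx(float(want))

    def test_continuous_abundance_allowed(self):
        val = edge_cohort_loglik(10, 25.7, 0.4)
        assert np.isfinite(val)

    def test_abundance_below_count_is_sentinel(self):
        with pytest.warns(UserWarning):
            assert edge_cohort_loglik(13, 12, 0.4) <= NEG_SENTINEL


class TestTelemetryLoglik:
    def _tel(self, rows):
        y, c, n, h = zip(*rows)
        return TelemetryData(np.array(y), np.array(c, dtype=object),
                             np.array(n), np.array(h))

    def test_binomial_oracle(self):
        tel = self._tel([(12, "pooled", 30, 12)])
        want = stats.binom.logpmf(12, 30, 0.4)
        assert telemetry_loglik(tel, {(12, "pooled"): 0.4}) == pytest.approx(float(want))

    def test_zero_at_risk_contributes_nothing(self):
        tel = self._tel([(12, "pooled", 0, 0)])
        assert telemetry_loglik(tel, {(12, "pooled"): 0.4}) == 0.0

    def test_zero_probability_with_harvest_is_sentinel(self):
        tel = self._tel([(12, "adult", 30, 3)])
        with pytest.warns(UserWarning):
            assert telemetry_loglik(tel, {(12, "adult"): 0.0}) <= NEG_SENTINEL

    def test_undefined_year_raises(self):
        tel = self._tel([(12, "adult", 30, 3)])
        with pytest.raises(ValueError, match="telemetry year"):
            telemetry_loglik(tel, {(11, "adult"): 0.4})


class TestCatchEffortLoglik:
    def test_pmf_oracle(self):
        want = stats.binom.logpmf(40, 100, 0.4)
        assert catch_effort_loglik([40], [100], [0.4]) == pytest.approx(float(want))

    def test_exhaustive_case(self):
        assert catch_effort_loglik([50], [50], [1.0]) == 0.0

    def test_zero_harvest_closed_form(self):
        assert catch_effort_loglik([0], [120], [0.3]) == pytest.approx(120 * np.log(0.7))

    def test_abundance_below_harvest_is_sentinel(self):
        with pytest.warns(UserWarning):
            assert catch_effort_loglik([60], [50], [0.5]) <= NEG_SENTINEL


class TestRePenalty:
    def test_standard_normal_at_zero(self):
        Y = 7
        want = Y * stats.norm.logpdf(0.0, scale=1.0)
        assert re_penalty(delta=np.zeros(Y), sigma_s=1.0) == pytest.approx(float(want))

    def test_one_sd_value(self):
        want = stats.norm.logpdf(0.3, scale=0.3)
        assert re_penalty(nu=[0.3], sigma_c=0.3) == pytest.approx(float(want))

    def test_fixed_effects_model_contributes_zero(self):
        assert re_penalty() == 0.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            re_penalty(delta=[0.1], sigma_s=0.0)
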