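import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from popreconstruct.process import (CohortLayout, ParameterState,
                                    build_cohort_layout, expected_harvest,
                                    harvest_probability, survival)


class _Data:
    def __init__(self, effort):
        self.effort = np.asarray(effort, dtype=float)


class TestHarvestProbability:
    def test_zero_effort_means_no_harvest(self):
        assert harvest_probability(0.5, 0.0) == 0.0

    def test_closed_form_inversion_gives_base_rate(self):
        # c f = -ln(0.6) makes the harvest probability at mean effort 0.40
        assert harvest_probability(-np.log(0.6), 1.0) == pytest.approx(0.400)

    def test_limit_in_random_effect(self):
        assert harvest_probability(0.5, 1.0, nu=40.0) == pytest.approx(1.0)

    @given(st.floats(-2, 2), st.floats(-2, 2))
    def test_strictly_monotone_in_nu(self, nu1, nu2):
        if abs(nu1 - nu2) < 1e-6:
            return
        lo, hi = sorted([nu1, nu2])
        assert harvest_probability(0.5, 1.0, lo) < harvest_probability(0.5, 1.0, hi)

    def test_nonpositive_vulnerability_rejected(self):
        with pytest.raises(ValueError):
            harvest_probability(0.0, 1.0)


class TestSurvival:
    def test_identity_at_zero_effect(self):
        assert survival(0.37) == pytest.approx(0.37)

    @pytest.mark.parametrize("delta,expected", [
        (-0.2, 0.450), (0.2, 0.550), (-0.6, 0.354), (0.6, 0.646),
    ])
    def test_two_sigma_envelopes(self, delta, expected):
        assert survival(0.5, delta) == pytest.approx(expected, abs=5e-4)

    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_strictly_monotone_in_delta(self, d1, d2):
        if abs(d1 - d2) < 1e-6:
            return
        lo, hi = sorted([d1, d2])
        assert survival(0.5, lo) < survival(0.5, hi)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            survival(1.0)


class TestCohortLayout:
    def test_smallest_case(self):
        lay = build_cohort_layout(2)
        assert lay.cohorts[0] == ((1, "A"), (2, "A"))
        assert lay.cohorts[1] == ((1, "J"), (2, "A"))
        assert lay.cohorts[2] == ((2, "J"),)

    def test_interior_cohort_cells(self):
        lay = build_cohort_layout(3)
        assert lay.cohorts[1] == ((1, "J"), (2, "A"), (3, "A"))

    def test_every_cell_covered(self):
        lay = build_cohort_layout(10)
        juv = {}
        adults = set()
        for cells in lay.cohorts:
            for (year, cls) in cells:
                if cls == "J":
                    juv[year] = juv.get(year, 0) + 1
                else:
                    adults.add(year)
        # juvenile cells belong to exactly one cohort; pooled adult cells are
        # shared composites but every year's cell is reached
        assert juv == {y: 1 for y in range(1, 11)}
        assert adults == set(range(1, 11))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            build_cohort_layout(1)


class TestExpectedHarvest:
    def _params(self, Y, s=0.5, P=0.4):
        return ParameterState(s_base=s, c_base=-np.log1p(-P),
                              delta=np.zeros(Y), nu=np.zeros(Y))

    def test_hand_chain(self):
        lay = build_cohort_layout(3)
        out = expected_harvest(self._params(3), _Data(np.ones(3)), lay,
                               [1000.0, 1000.0, 1000.0, 1000.0])
        # entry cells
        np.testing.assert_allclose(out[:, 0], 400.0)
        # one survival/harvest step: 1000 * 0.6 * 0.5 * 0.4 = 120
        assert out[1, 1] == pytest.approx(240.0)   # cohorts 1 and 2
        assert out[2, 1] == pytest.approx(36 + 36 + 120)

    def test_no_survival_kills_downstream(self):
        lay = build_cohort_layout(3)
        out = expected_harvest(self._params(3, s=1e-12), _Data(np.ones(3)), lay,
                               [500.0] * 4)
        np.testing.assert_allclose(out[:, 1], [200.0, 0.0, 0.0], atol=1e-6)

    def test_exhaustive_harvest(self):
        lay = build_cohort_layout(3)
        params = ParameterState(s_base=0.5, c_base=40.0,
                                delta=np.zeros(3), nu=np.zeros(3))
        out = expected_harvest(params, _Data(np.ones(3)), lay, [100.0] * 4)
        np.testing.assert_allclose(out[:, 0], 100.0)
        np.testing.assert_allclose(out[1:, 1], 0.0, atol=1e-10)

    @given(st.floats(0.1, 5.0))
    def test_homogeneous_of_degree_one(self, scale):
        lay = build_cohort_layout(4)
        base = np.array([300.0, 200.0, 250.0, 220.0, 180.0])
        p = self._params(4)
        d = _Data(np.ones(4))
        out1 = expected_harvest(p, d, lay, base)
        out2 = expected_harvest(p, d, lay, base * scale)
        np.testing.assert_allclose(out2, out1 * scale, rtol=1e-10)

    def test_cohort_total_bounded_by_entry(self):
        lay = build_cohort_layout(6)
        entries = np.full(7, 1000.0)
        p = self._params(6, s=0.9, P=0.5)
        out = expected_harvest(p, _Data(np.ones(6)), lay, entries)
        assert out.sum() <= entries.sum() + 1e-9
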