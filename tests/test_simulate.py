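import dataclasses

import numpy as np
import pytest

from popreconstruct.simulate import (SimulationConfig, apply_scenario,
                                     simulate_population, simulate_telemetry,
                                     stationary_recruits_per_adult)


class TestCalibration:
    def test_stationary_recruits_at_base_parameters(self):
        assert stationary_recruits_per_adult(0.5, 0.4) == pytest.approx(7 / 3)

    def test_noiseless_projection_is_stationary(self):
        """Expected-value dynamics drift less than 1% over 1000 years."""
        g = (1 - 0.4) * 0.5
        r = stationary_recruits_per_adult(0.5, 0.4)
        J, A = 28_000.0, 12_000.0
        for _ in range(1000):
            J, A = r * A, g * (J + A)
        assert abs((J + A) / 40_000.0 - 1.0) < 0.01

    def test_zero_variation_population_stays_near_target(self):
        cfg = SimulationConfig(sigma_level=0.0, seed=4)
        pop = simulate_population(cfg)
        assert np.all(np.abs(pop.total_abundance / 40_000.0 - 1.0) < 0.20)


class TestStochasticStructure:
    def test_same_seed_reproduces(self):
        cfg = SimulationConfig(sigma_level=0.2, seed=9)
        p1 = simulate_population(cfg)
        p2 = simulate_population(cfg)
        np.testing.assert_array_equal(p1.juvenile_harvest, p2.juvenile_harvest)
        np.testing.assert_array_equal(p1.adult_abundance, p2.adult_abundance)
        t1 = simulate_telemetry(p1)
        t2 = simulate_telemetry(p2)
        np.testing.assert_array_equal(t1.n_harvested, t2.n_harvested)

    def test_harvest_never_exceeds_abundance(self):
        pop = simulate_population(SimulationConfig(sigma_level=0.3, seed=5))
        assert np.all(pop.juvenile_harvest <= pop.juvenile_abundance)
        assert np.all(pop.adult_harvest <= pop.adult_abundance)

    def test_adults_bounded_by_survivor_pool(self):
        pop = simulate_population(SimulationConfig(sigma_level=0.2, seed=6))
        pool = (pop.juvenile_abundance + pop.adult_abundance
                - pop.juvenile_harvest - pop.adult_harvest)
        assert np.all(pop.adult_abundance[1:] <= pool[:-1])

    @pytest.mark.parametrize("sigma,lo,hi", [
        (0.1, 0.450, 0.550), (0.2, 0.401, 0.599), (0.3, 0.354, 0.646),
    ])
    def test_survival_two_sigma_envelopes(self, sigma, lo, hi):
        vals = np.concatenate([
            simulate_population(SimulationConfig(sigma_level=sigma, seed=s)).true_survival
            for s in range(120)])
        # Table-2 envelopes are +/-2 sigma endpoints: probability points 2.275/97.725
        q = np.percentile(vals, [2.275, 97.725])
        assert q[0] == pytest.approx(lo, abs=0.02)
        assert q[1] == pytest.approx(hi, abs=0.02)

    @pytest.mark.parametrize("sigma,lo,hi", [
        (0.1, 6.050, 9.025), (0.2, 4.953, 11.023), (0.3, 4.055, 13.464),
    ])
    def test_fecundity_two_sigma_envelopes(self, sigma, lo, hi):
        cfgs = [SimulationConfig(sigma_level=sigma, seed=s) for s in range(120)]
        r_star = stationary_recruits_per_adult(0.5, 0.4)
        phi = r_star / (cfgs[0].base_fecundity * np.exp(0.5 * sigma**2))
        vals = np.concatenate([simulate_population(c).true_recruit_rate / phi
                               for c in cfgs])
        q = np.percentile(vals, [2.275, 97.725])
        assert q[0] == pytest.approx(lo, rel=0.03)
        assert q[1] == pytest.approx(hi, rel=0.03)


class TestScenarios:
    def test_baseline_is_identity(self):
        mods = apply_scenario(SimulationConfig(scenario="baseline"))
        assert np.all(mods["recruit_multiplier"] == 1.0)
        assert np.ptp(mods["logit_survival"]) == 0.0

    def test_increasing_trend_direction(self):
        pop = simulate_population(SimulationConfig(scenario="increasing_S",
                                                   sigma_level=0.1, seed=7))
        assert pop.true_survival[-5:].mean() > pop.true_survival[:5].mean()

    def test_decreasing_trend_direction(self):
        pop = simulate_population(SimulationConfig(scenario="decreasing_S",
                                                   sigma_level=0.1, seed=7))
        assert pop.true_survival[-5:].mean() < pop.true_survival[:5].mean()

    def test_periodic_recruitment_pulses(self):
        cfg = SimulationConfig(scenario="periodic_recruitment", sigma_level=0.1)
        mods = apply_scenario(cfg)
        kept = mods["recruit_multiplier"][-cfg.keep_years:]
        years = np.arange(1, cfg.keep_years + 1)
        assert np.all(kept[years % 4 == 0] > 1.0)
        assert np.all(kept[years % 4 == 2] < 1.0)
        assert np.all(kept[years % 2 == 1] == 1.0)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(scenario="boom_bust")


class TestTelemetryDesigns:
    def test_single_year_design(self):
        pop = simulate_population(SimulationConfig(telemetry_design="1yr", seed=2))
        tel = simulate_telemetry(pop)
        assert list(tel.year) == [12]
        assert list(tel.n_at_risk) == [30]

    def test_six_year_design(self):
        pop = simulate_population(SimulationConfig(telemetry_design="6yr", seed=2))
        tel = simulate_telemetry(pop)
        assert list(tel.year) == [9, 10, 11, 12, 13, 14]
        assert np.all(tel.n_at_risk == 30)
        assert np.all(tel.n_harvested <= 30)


def test_extinction_is_reported_not_hidden():
    extinct = 0
    for seed in range(40):
        cfg = SimulationConfig(sigma_level=0.3, target_abundance=6, seed=seed)
        try:
            simulate_population(cfg)
        except RuntimeError as exc:
            assert "re-seed" in str(exc)
            extinct += 1
    assert extinct > 0
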