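"""Simulate a small-game population and reconstruct it.

Generates 25 years of age-at-harvest data from the stochastic Leslie-matrix
simulator (low interannual variation, six years of radiotelemetry), fits the
random-effects Horvitz-Thompson model, and compares the reconstruction with
the simulated truth.
"""

import numpy as np

from popreconstruct import (ModelSpec, SimulationConfig, fit,
                            simulate_population, simulate_telemetry)

cfg = SimulationConfig(sigma_level=0.1, telemetry_design="6yr", seed=7)
pop = simulate_population(cfg)
tel = simulate_telemetry(pop)

result = fit(ModelSpec("HT", "RE"), pop.to_age_at_harvest(), tel)

fbar = float(np.mean(pop.effort))
print("true survival 0.50, estimated "
      f"{result.params['s_base']:.3f} (SE {result.se['s_base']:.3f})")
print("true harvest rate at mean effort 0.40, estimated "
      f"{1 - np.exp(-result.params['c'] * fbar):.3f}")
print(f"interannual sd estimates: survival {result.params['sigma_s']:.3f}, "
      f"vulnerability {result.params['sigma_c']:.3f} (true 0.1 each)")

est = result.abundance["estimate"].to_numpy()
truth = pop.total_abundance
inside = ((truth >= result.abundance["lo95"]) & (truth <= result.abundance["hi95"]))
print(f"\nmean abundance error {np.mean(100 * (est - truth) / truth):+.1f}%; "
      f"{inside.sum()}/{len(truth)} years inside the 95% CI")
for i in (0, 12, 24):
    print(f"  year {i + 1:2d}: true {truth[i]:6,} reconstructed {est[i]:8,.0f}")
# The Horvitz-Thompson series tracks the true trajectory within a few percent;
# interval coverage is close to nominal at this variation level.
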