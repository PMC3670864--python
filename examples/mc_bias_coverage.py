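"""A miniature Monte Carlo performance study.

Runs a few replicates of the simulate-and-refit experiment for the
random-effects Horvitz-Thompson model and the fixed-effects absolute-abundance
model (with the catch-effort auxiliary) and prints the median relative bias of
total abundance and the 95% CI coverage.  Increase ``n_reps`` (the published
study used 1,000) for stable numbers; 10 replicates keep this example quick.
"""

from popreconstruct import ModelSpec, run_mc_study

df = run_mc_study(
    models=[ModelSpec("HT", "RE"),
            ModelSpec("AA", "FE", include_catch_effort=True)],
    sigma_levels=(0.0, 0.2),
    telemetry_designs=("1yr",),
    n_reps=10,
    seed=1,
)
cols = ["model", "catch_effort", "sigma", "mean_mrb", "coverage", "n_failed"]
print(df[cols].to_string(index=False, float_format=lambda v: f"{v:.1f}"))
# mean_mrb is the across-year mean of the median relative (percent) bias of
# total annual abundance; coverage is the percent of (replicate, year) pairs
# whose asymptotic 95% CI contains the true abundance.  The HT_RE model stays
# near 0% bias with near-nominal coverage; the rigid AA_FE model's intervals
# ignore the interannual variation and cover far less often.
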