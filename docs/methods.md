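# Methods

This note records the statistical model implemented by `popreconstruct`, the
numerical choices behind the fits, what the synthetic-data generator does and
does not emulate, and the design decisions taken where the formulation was
genuinely open.

## The reconstruction model

Data are a Y×2 age-at-harvest matrix — juvenile (young-of-the-year) and
pooled adult (A+) harvest counts x_{i,J}, x_{i,A} per year — an annual
hunter-effort series f_i, and radiotelemetry records (animals at risk and
harvested, by year and optionally by age class).  Demographic rates:

* harvest probability `P_i = 1 − exp(−c f_i e^{ν_i})` (catch-effort form);
* annual natural survival `s_i = logit⁻¹(logit(s̄) + δ_i)`;
* random effects δ_i ~ N(0, σ_s²), ν_i ~ N(0, σ_c²), mutually independent.

Only `c·f` is identified, so effort units are arbitrary; the simulator
normalizes mean effort to 1, and the turkey application uses units of 10,000
hunter trips.

### Conditional age-at-harvest likelihood

Cohort j enters the matrix as the juvenile cell of year j−1 and contributes
to the pooled adult cell of every later year; cohort 1 is the adult stock at
study start.  Expected cell counts propagate entry abundances through the
harvest process: the animals that survive year i's harvest are those not in
the observed catch, and they survive the non-harvest season with probability
s_i:

    A_{i+1} = (A_i + J_i − x_{i,J} − x_{i,A}) · s_i ,
    E[x_{i,J}] = J_i P_i ,     E[x_{i,A}] = A_i P_i .

The primary component conditions on harvest: given the total count over the
interior cells (juvenile cells of years 1..Y−1 and adult cells of years
2..Y), the counts are multinomial with probabilities proportional to the
expected counts.  Combinatorial constants are retained so AIC values are
comparable.  Two conditioning schemes are implemented:

* `pooled` (default): one multinomial over all interior cells, conditioning
  on the study-wide total.  Each observation is used once and the implied
  information matrix produced near-nominal interval coverage in the
  simulation study.
* `per_cohort`: one multinomial per entering cohort over {its juvenile cell,
  all later pooled adult cells}, the literal cohort-group reading.  Because
  every pooled adult cell re-appears in up to Y−1 groups, this is a
  composite (pseudo-)likelihood that overstates information; point estimates
  are essentially unchanged but intervals shrink unrealistically.  It is kept
  for comparison via the `grouping` option.

The two edge cohorts (initial adults, final-year juveniles) have no interior
cohort structure.  In AA models they enter as absolute binomials
Bin(x | N, P), which supplies abundance-scale information; in HT models the
corresponding binomial would be self-fulfilling (N is the plug-in x/P) and
is omitted — those cells are degenerate single-cell conditional components.

### Abundance

* **HT models**: cohort entry abundances are Horvitz–Thompson plug-ins
  `x/P` evaluated at the *current* parameters and substituted directly into
  the recursion (with N = x/P, observed-catch subtraction and the expected
  form N(1−P) coincide).  The reported annual abundance is the per-cell HT
  sum N̂_i = x_{i,J}/P̂_i + x_{i,A}/P̂_i at the empirical Bayes effects.
  Freezing the plug-ins between outer iterations — a literal EM — was tried
  and rejected: the resulting fixed-point map has spurious degenerate
  attractors under strong interannual variation (survival driven to 1,
  variance components to their bounds, abundance bias near +100%).
* **AA models**: all Y+1 entry abundances are free parameters; the observed
  subtraction makes the conditional multinomial informative about absolute
  scale (change-in-ratio information).  AA_FE additionally requires the
  catch-effort auxiliary — total harvest ~ Bin(N_i, P_i) with model-implied
  N_i — to be fit stably at all.
* The catch-effort auxiliary for HT models keeps the published EM form: its
  abundance is plugged in as data and refreshed in an outer loop (tolerance
  1e-6 on total abundance, at most 100 iterations, with a stall detector).
  As in the source study, including it biases the HT estimates upward, and
  it is off by default.

### Marginal likelihood and uncertainty

Random effects are integrated out by a Laplace approximation: the inner mode
(the empirical Bayes prediction) is found by damped Newton iterations with
analytic gradients; the Hessian is a central finite difference of that
gradient.  The approximation is exact for linear-Gaussian inner problems and
is validated against closed-form marginals to 1e-6.  The outer optimizer is
L-BFGS-B on transformed parameters (logit survival, log vulnerability, log
standard deviations, log abundances) with variance components bounded in
[1e-3, 3].  The outer finite-difference gradient is evaluated in a single
vectorized pass: each perturbation's inner mode is reached with one Newton
step from the central mode (second-order accurate), then the joint
likelihood and log-determinant are re-evaluated there.

Parameter SEs come from the inverse Hessian of the marginal (or joint, for
FE models) negative log-likelihood in natural parameters; parameters at
bounds are profiled out.  Annual abundance variance is the sum of

1. the delta-method term ∇N̂ᵀ H⁻¹ ∇N̂ over the fixed effects (with the inner
   mode re-solved at each perturbed value),
2. the second-stage Horvitz–Thompson binomial component Σ x(1−P̂)/P̂², and
3. the conditional prediction variance of the empirical Bayes vulnerability
   effects, gᵀ H_inner⁻¹ g — zero when variance components vanish, material
   at high variation, where omitting it costs several points of interval
   coverage.

Confidence intervals are symmetric, N̂ ± 1.96 SE.  Binomial likelihoods with
non-integer abundance use the continuous gammaln relaxation throughout so
the objective stays differentiable.  Impossible configurations return a
±1e10 sentinel with a warning rather than raising inside optimizers.

## The two-season turkey model

The Missouri application adds structure: separate vulnerabilities c_J, c_A
with separate lognormal random effects (the selected model has no survival
random effect), a single annual survival split into a 22-week summer and a
24-week winter interval (s^{22/46}, s^{24/46}, composing exactly to the
annual rate), and known removals.  Event order within a year: spring
non-permittee removals → permitted spring harvest → juveniles graduate to
the adult class → summer survival → fall harvest (a known removal; fall
*juvenile* removals never enter because poult abundance is unobservable) →
winter survival → next spring.  Spring abundance adds the spring removals
back onto the per-class HT estimates.  Fall-removal variability is ignored,
so abundance uncertainty is slightly understated.

Model selection ranks candidate fixed-effect structures by AIC and tests
variance components on the boundary with the 50:50 χ²₀:χ²₁ mixture
(p-value 1 at statistic 0 by convention).

A caution for interpreting the turkey fit: the profile likelihood in annual
survival is nearly flat across a wide range, because survival trades off
against juvenile vulnerability in supplying next year's adults.  Point
estimates anywhere on that ridge are statistically equivalent; the wide
interval (roughly ±30 percentage points) is the meaningful statement.

## The simulator and what passing tests mean

The generator is a stochastic two-class Leslie matrix: binomial harvest and
binomial survival per class and year with shared s_i and P_i, Poisson
recruitment linear in the pre-season adult stock, lognormal interannual
variation (common σ per level: 0, 0.1, 0.2, 0.3) on survival (logit scale),
vulnerability and fecundity, effort with 5% lognormal jitter around its
mean.  Base conditions: s̄ = 0.5, harvest rate 0.40 at mean effort,
fecundity e² ≈ 7.39 young per adult (the value whose lognormal ±2σ
envelopes match the reported ones).  A pre-recruitment survival factor
calibrates the expected growth rate to exactly 1 — it also absorbs the
lognormal mean e^{σ²/2} so the population stays stationary in expectation at
every variation level — giving ≈ 2.33 effective recruits per adult and a
stationary population of ≈ 40,000 (70% juvenile).  The population evolves
for 75 years and the final 25 form the dataset; telemetry tags 30 animals in
kept year 12 (single-year design) or in each of years 9–14.

Robustness scenarios act on the kept years at the low variation level:
survival ramps linearly between 0.45 and 0.55 on the logit scale
(increasing/decreasing), or recruitment is multiplied by 1.5 in kept years
4, 8, 12, … and by 0.5 in years 2, 6, 10, … (amplitudes are this package's
choice; the scenario descriptions fix only the shape).

The simulator deliberately omits density dependence, sex structure,
age-specific rates within the pooled class, harvest reporting error and
effort measurement error.  Passing the Monte Carlo checks therefore shows
that the estimator recovers truth when its structural assumptions hold (and
under the three scripted violations) — not that it is robust to the many
ways real harvest data depart from them.

## Problem sizes and seeds

The Monte Carlo harness defaults to desk scale: 100 replicates per grid
cell (the original study used 1,000), which puts the Monte Carlo standard
error of a coverage estimate near 1–2 percentage points and of mean MRB near
1–2 points.  Replicate r of a cell seeded with m uses master seed m + r;
population and telemetry consume separate sub-streams.  Failed or
unconverged fits are excluded and tallied.  All fits are deterministic given
data and initialization (s̄ = 0.5, harvest rate 0.3 at mean effort — 0.1
for turkey juveniles — σ = 0.1, abundances harvest/0.3; overridable).

## Known limitations

* The Laplace approximation is unchecked against exact integration for the
  non-Gaussian inner problems it is actually used on (standard practice, but
  worth stating).
* AA models are poorly identified in this two-class setting: AA_RE is
  negatively biased and AA_FE, although its interval coverage collapses as
  expected once interannual variation exists, also shows substantial
  negative abundance bias here.  They are provided for comparison, not use.
* With a single year of telemetry the harvest-probability level rests on 30
  animals; estimates are correspondingly noisy, and the random-effect
  variance split between survival and vulnerability can be bimodal across
  replicates.  In roughly one replicate in ten at zero variation the
  propagated cohort expectations supply confident but wrong level
  information (the persistence pattern of the pooled adult series), which
  pulls interval coverage a few points below nominal and leaves a small
  positive median abundance bias at low variation; both effects disappear
  with six telemetry years.
* Effort is treated as known; the turkey effort SEs are carried as metadata
  only.
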