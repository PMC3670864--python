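"""Likelihood components for age-at-harvest reconstruction.

The primary component is a conditional ("ever harvested") cohort likelihood:
given the total harvest of a cohort, the cell counts are multinomial with
probabilities proportional to the expected harvest counts.  Auxiliary
components are binomial: radiotelemetry harvests of tagged animals,
the catch-effort likelihood (total annual harvest as a binomial sample from
total annual abundance), and absolute binomial contributions for the two edge
cohorts that have no interior cohort structure.  Random effects enter through
independent mean-zero normal penalty terms.

Log-likelihoods that would be -inf (a zero-probability cell with a positive
count, or an abundance below an observed count) are returned as the large
negative sentinel ``NEG_SENTINEL`` with a warning so optimizers can recover.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln

__all__ = [
    "NEG_SENTINEL",
    "conditional_cell_probs",
    "cohort_loglik",
    "edge_cohort_loglik",
    "binomial_loglik",
    "telemetry_loglik",
    "catch_effort_loglik",
    "re_penalty",
]

NEG_SENTINEL = -1e10

_LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateLikelihoodWarning(UserWarning):
    """A likelihood component was driven to an impossible configuration."""


def _sentinel(msg: str) -> float:
    warnings.warn(msg, DegenerateLikelihoodWarning, stacklevel=3)
    return NEG_SENTINEL


def conditional_cell_probs(expected) -> np.ndarray:
    """Normalize expected harvest counts into per-cell conditional probabilities.

    ``p_i = E[x_i] / sum(E[x])`` — the probability that a cohort member is
    harvested in cell i given that it is ever harvested.
    """
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected counts must be non-negative")
    total = expected.sum()
    if not total > 0:
        raise ValueError("degenerate cohort: total expected harvest is zero")
    return expected / total


def cohort_loglik(x, probs) -> float:
    """Multinomial log-likelihood of a cohort's cell counts given its total.

    Equivalent to the product of sequential conditional binomials down the
    cohort; the combinatorial constant is retained so that AIC values are
    comparable across models.  Fates of animals within a cohort and year are
    assumed independent.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(probs, dtype=float)
    if x.shape != p.shape:
        raise ValueError("counts and probabilities must have equal length")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("probabilities must be non-negative and sum to 1")
    if np.any((p == 0) & (x > 0)):
        return _sentinel("cohort cell with zero probability but positive count")
    n = x.sum()
    const = gammaln(n + 1.0) - gammaln(x + 1.0).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        core = np.where(x > 0, x * np.log(np.where(p > 0, p, 1.0)), 0.0).sum()
    return float(const + core)


def binomial_loglik(x, n, p) -> float:
    """Binomial log-pmf with a continuous (gammaln) relaxation in ``n``.

    ``n`` may be non-integer (e.g. a Horvitz-Thompson abundance estimate used
    as data); gradients are taken on this continuous relaxation.
    """
    x = float(x)
    n = float(n)
    p = float(p)
    if x < 0 or n < 0:
        raise ValueError("counts must be non-negative")
    if n == 0:
        return 0.0
    if n < x:
        return _sentinel(f"binomial abundance {n:.3f} below observed count {x:.0f}")
    if p <= 0.0:
        return 0.0 if x == 0 else _sentinel("zero harvest probability with positive count")
    if p >= 1.0:
        return 0.0 if x == n else _sentinel("unit harvest probability with survivors")
    const = gammaln(n + 1.0) - gammaln(x + 1.0) - gammaln(n - x + 1.0)
    return float(const + x * np.log(p) + (n - x) * np.log1p(-p))


def edge_cohort_loglik(x, n_available, p) -> float:
    """Absolute binomial contribution for an edge cohort cell.

    The first cohort (pooled adults at study start) and the last cohort (the
    final year's juveniles) have no interior cohort structure, so they enter
    the likelihood as ``Binomial(x | N, P)`` components (``N`` a parameter for
    AA models, a Horvitz-Thompson plug-in for HT models).
    """
    return binomial_loglik(x, n_available, p)


def telemetry_loglik(telemetry, harvest_prob) -> float:
    """Sum of binomial log-pmfs for tagged-animal harvests.

    ``harvest_prob`` maps a (year, age_class) pair to the harvest probability
    of unmarked animals of that class in that year (a callable or a dict).
    Records with zero animals at risk contribute nothing.
    """
    lookup = harvest_prob if callable(harvest_prob) else (lambda y, c: harvest_prob[(y, c)])
    total = 0.0
    for year, cls, n, h in zip(telemetry.year, telemetry.age_class,
                               telemetry.n_at_risk, telemetry.n_harvested):
        if n == 0:
            continue
        try:
            p = float(lookup(int(year), str(cls)))
        except KeyError:
            raise ValueError(f"no harvest probability defined for telemetry year {year}, {cls}")
        ll = binomial_loglik(h, n, p)
        if ll <= NEG_SENTINEL:
            return NEG_SENTINEL
        total += ll
    return total


def catch_effort_loglik(total_harvest, n_total, harvest_prob) -> float:
    """Auxiliary catch-effort likelihood: annual harvest ~ Bin(N_i, P_i).

    For HT models ``n_total`` is the current Horvitz-Thompson estimate plugged
    in as data (the EM form); for AA models it is the model-implied abundance.
    """
    total_harvest = np.atleast_1d(np.asarray(total_harvest, dtype=float))
    n_total = np.atleast_1d(np.asarray(n_total, dtype=float))
    p = np.atleast_1d(np.asarray(harvest_prob, dtype=float))
    total = 0.0
    for x, n, pi in zip(total_harvest, n_total, p):
        ll = binomial_loglik(x, n, pi)
        if ll <= NEG_SENTINEL:
            return NEG_SENTINEL
        total += ll
    return total


def re_penalty(delta=None, nu=None, sigma_s=None, sigma_c=None) -> float:
    """Normal log-density of the random effects: sum log N(u_i; 0, sigma^2).

    A fixed-effects model (no effects supplied) contributes exactly zero.
    """
    total = 0.0
    for u, sigma, name in ((delta, sigma_s, "sigma_s"), (nu, sigma_c, "sigma_c")):
        if u is None or len(np.atleast_1d(u)) == 0:
            continue
        if sigma is None or sigma <= 0:
            raise ValueError(f"{name} must be positive when its random effects are present")
        u = np.asarray(u, dtype=float)
        total += float(-0.5 * np.sum(u**2) / sigma**2
                       - len(u) * (np.log(sigma) + 0.5 * _LOG_2PI))
    return total
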