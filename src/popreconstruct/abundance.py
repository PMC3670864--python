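"""Horvitz-Thompson and absolute-abundance estimators.

The second-stage Horvitz-Thompson estimator scales each observed harvest count
by its estimated harvest probability, ``N = x / P``, applied individually to
every cell of the age-at-harvest matrix; it is first-order unbiased under the
binomial harvest assumption and requires no cohort-structure information.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["ht_cell_abundance", "total_annual_abundance", "pooled_harvest_probability"]


def ht_cell_abundance(x, P):
    """Horvitz-Thompson estimate ``x / P`` for one (or many) matrix cells."""
    x = np.asarray(x, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any((P <= 0) & (x > 0)):
        raise ValueError("zero harvest probability with a positive harvest count")
    if np.any(P > 1):
        raise ValueError("harvest probability above 1")
    if np.any((P <= 0) & (x == 0)):
        warnings.warn("zero harvest probability with zero count: abundance set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(P > 0, x / np.where(P > 0, P, 1.0), 0.0)
    return out if out.ndim else float(out)


def pooled_harvest_probability(xJ, xA, PJ, PA):
    """Harvest-weighted pooled probability across age classes.

    Defined so that total harvest divided by the pooled probability equals the
    sum of the per-class Horvitz-Thompson estimates.
    """
    n = ht_cell_abundance(xJ, PJ) + ht_cell_abundance(xA, PA)
    tot = np.asarray(xJ, dtype=float) + np.asarray(xA, dtype=float)
    return np.where(n > 0, tot / np.where(n > 0, n, 1.0), 0.0)


def total_annual_abundance(fit_result, data) -> np.ndarray:
    """Per-year total abundance implied by a fit.

    HT models: per-cell Horvitz-Thompson estimates summed over age classes.
    AA models: entry abundances propagated through the fitted
    harvest/survival recursion, summing the age classes.
    """
    spec = fit_result.spec
    if spec is not None and spec.abundance_mode == "AA":
        from .fitting import _aa_total_abundance
        engine = fit_result.extra["engine"]
        u = fit_result.extra["objective"].eb_mode(fit_result.extra["x"])
        return _aa_total_abundance(engine, u)
    P = fit_result.harvest_prob
    return ht_cell_abundance(data.juvenile_harvest, P) + ht_cell_abundance(data.adult_harvest, P)
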