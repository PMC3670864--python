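"""Demographic process functions.

Harvest follows the catch-effort form ``P_i = 1 - exp(-c f_i e^{nu_i})`` where
``c`` is the harvest vulnerability coefficient, ``f_i`` the annual hunter
effort and ``nu_i`` a lognormal-scale temporal random effect.  Natural
(non-harvest-season) survival is ``s_i = expit(logit(s_base) + delta_i)`` with
``delta_i`` a logit-scale temporal random effect.  Cohorts in a two-age-class
(juvenile / pooled adult) harvest matrix run down diagonals: cohort j enters as
the juvenile class in year j-1 and contributes to the pooled adult cell of
every later year; cohort 1 is the pooled adult stock present at study start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "harvest_probability",
    "survival",
    "ParameterState",
    "CohortLayout",
    "build_cohort_layout",
    "expected_harvest",
]


def harvest_probability(c, f, nu=0.0):
    """Probability of harvest ``1 - exp(-c f e^nu)``; in [0, 1).

    Strictly increasing in ``nu`` and in ``f``; zero effort gives zero harvest.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("vulnerability coefficient c must be positive")
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("effort must be non-negative")
    return -np.expm1(-c * f * np.exp(np.asarray(nu, dtype=float)))


def survival(s_base, delta=0.0):
    """Annual natural survival ``expit(logit(s_base) + delta)``; in (0, 1)."""
    s_base = np.asarray(s_base, dtype=float)
    if np.any(s_base <= 0) or np.any(s_base >= 1):
        raise ValueError("s_base must lie strictly inside (0, 1)")
    return expit(logit(s_base) + np.asarray(delta, dtype=float))


@dataclass(frozen=True)
class ParameterState:
    """Fixed effects, variance components and per-year random effects.

    ``n0`` (initial cohort abundances, length Y+1, cohort 1 first) is present
    only for absolute-abundance (AA) models; HT models obtain entry abundances
    from the second-stage Horvitz-Thompson plug-ins instead.
    """

    s_base: float
    c_base: float
    sigma_s: float = 0.0
    sigma_c: float = 0.0
    delta: np.ndarray | None = None
    nu: np.ndarray | None = None
    n0: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 < self.s_base < 1.0:
            raise ValueError("s_base must lie in (0, 1)")
        if self.c_base <= 0:
            raise ValueError("c_base must be positive")
        if self.sigma_s < 0 or self.sigma_c < 0:
            raise ValueError("standard deviations must be non-negative")
        for name in ("delta", "nu", "n0"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))

    def effects(self, n_years: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (delta, nu) padded with zeros when absent."""
        delta = np.zeros(n_years) if self.delta is None else self.delta
        nu = np.zeros(n_years) if self.nu is None else self.nu
        if len(delta) != n_years or len(nu) != n_years:
            raise ValueError("random-effect vectors must have one entry per year")
        return delta, nu


@dataclass(frozen=True)
class CohortLayout:
    """Cells occupied by each chronologically numbered cohort (1-based years).

    ``cohorts[j-1]`` lists the (year, age_class) cells cohort j contributes to,
    with age_class 'J' or 'A'.  Pooled adult cells are shared between cohorts:
    every adult cell is a composite of all cohorts alive in that year.
    """

    n_years: int
    cohorts: tuple[tuple[tuple[int, str], ...], ...]

    @property
    def n_cohorts(self) -> int:
        return len(self.cohorts)

    def entry_cell(self, j: int) -> tuple[int, str]:
        """First cell of cohort j (1-based)."""
        return self.cohorts[j - 1][0]


def build_cohort_layout(n_years: int) -> CohortLayout:
    """Layout of the Y x 2 matrix into Y+1 overlapping cohort diagonals.

    Cohort 1 (the pooled adults at study start) occupies the Y adult cells;
    cohort j for 2 <= j <= Y enters as the juvenile cell of year j-1 and the
    adult cells of years j..Y; cohort Y+1 is the final year's juvenile cell.
    """
    if n_years < 2:
        raise ValueError("need at least 2 years for a cohort layout")
    cohorts = [tuple((i, "A") for i in range(1, n_years + 1))]
    for j in range(2, n_years + 1):
        cells = [(j - 1, "J")] + [(i, "A") for i in range(j, n_years + 1)]
        cohorts.append(tuple(cells))
    cohorts.append(((n_years, "J"),))
    return CohortLayout(n_years, tuple(cohorts))


def expected_harvest(params: ParameterState, data, layout: CohortLayout,
                     entry_abundance) -> np.ndarray:
    """Expected harvest counts, accumulated additively over cohorts.

    For each cohort with entry abundance N_j, the expected count in its entry
    cell is ``N_j P(entry year)``; animals alive after each year's harvest
    survive the non-harvest season (``alive * (1 - P_i) * s_i``) and are
    exposed again the following year, recursing down the cohort.  Pooled adult
    cells sum the contributions of every cohort present.  Returns a Y x 2
    matrix (columns: juvenile, adult); homogeneous of degree 1 in
    ``entry_abundance``.
    """
    Y = layout.n_years
    entry_abundance = np.asarray(entry_abundance, dtype=float)
    if len(entry_abundance) != layout.n_cohorts:
        raise ValueError("need one entry abundance per cohort")
    if np.any(entry_abundance < 0):
        raise ValueError("entry abundances must be non-negative")
    delta, nu = params.effects(Y)
    P = harvest_probability(params.c_base, data.effort, nu)
    s = survival(params.s_base, delta)
    out = np.zeros((Y, 2))
    col = {"J": 0, "A": 1}
    for j, cells in enumerate(layout.cohorts, start=1):
        alive = entry_abundance[j - 1]
        for k, (year, cls) in enumerate(cells):
            i = year - 1
            if k > 0:
                prev_i = cells[k - 1][0] - 1
                alive = alive * (1.0 - P[prev_i]) * s[prev_i]
            out[i, col[cls]] += alive * P[i]
    return out
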