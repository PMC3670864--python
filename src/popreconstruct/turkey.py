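"""Two-season wild-turkey population reconstruction (Missouri East Ozarks).

A spring-harvest age-at-harvest model with juvenile/adult-specific harvest
vulnerabilities, a single annual natural survival split into 22-week summer
and 24-week winter intervals, known removals (spring non-permittee removals
before the permitted season, fall harvests), per-class lognormal-scale
vulnerability random effects, and second-stage Horvitz-Thompson spring
abundance estimates.  The packaged East Ozarks male wild-turkey dataset
(1996-2010 harvests and effort, 1996-2000 radiotelemetry, removal series and
productivity indices) ships with the package.

Event order within a year: spring NPR removals -> permitted spring harvest ->
juveniles graduate to the adult class -> summer survival (22 wk) -> fall
harvest (known removal) -> winter survival (24 wk) -> next spring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._engine import TurkeyEngine
from .data import AgeAtHarvestData, RemovalData, TelemetryData
from .fitting import (FitResult, MarginalObjective, _maximize, _Packer,
                      fd_hessian_scalar)
from .process import harvest_probability, survival

__all__ = [
    "TurkeyModelSpec",
    "TurkeyDataset",
    "load_ozarks_east",
    "turkey_harvest_prob",
    "interval_survival",
    "expected_adults_next_year",
    "fit_turkey",
    "spring_abundance",
    "juvenile_spring_abundance",
    "poult_hen_comparison",
    "mixture_chi2_pvalue",
    "boundary_lrt",
    "model_selection",
]

log = logging.getLogger(__name__)

_Z95 = 1.959963984540054
SUMMER_WEEKS = 22
WINTER_WEEKS = 24
_YEAR_WEEKS = SUMMER_WEEKS + WINTER_WEEKS


@dataclass(frozen=True)
class TurkeyModelSpec:
    """Model structure for the turkey reconstruction.

    The selected model uses separate vulnerability coefficients with separate
    random effects per age class and no survival random effects.
    """

    separate_vulnerability: bool = True
    re_structure: tuple[str, ...] = ("vuln_juvenile", "vuln_adult")

    def __post_init__(self):
        for r in self.re_structure:
            if r not in ("vuln_juvenile", "vuln_adult", "survival"):
                raise ValueError(f"unknown random-effect structure {r!r}")


@dataclass(frozen=True)
class TurkeyDataset:
    harvest: AgeAtHarvestData
    telemetry: TelemetryData
    removals: RemovalData
    poult_hen: pd.Series     # includes the pre-study year
    archer_index: pd.Series


def load_ozarks_east() -> TurkeyDataset:
    """Load the packaged East Ozarks male wild-turkey dataset.

    Effort is in units of 10,000 hunter trips (the Results quote hunter-trip
    totals that imply this scale).  The 1997 effort SE is stored as 0.442; the
    source table prints "9,442", inconsistent with every other SE in the
    column, and is treated as a typo.  Effort SEs are metadata only.
    """
    with resources.files("popreconstruct.datasets").joinpath(
            "ozarks_east_turkey.csv").open() as fh:
        df = pd.read_csv(fh)
    study = df.dropna(subset=["spring_harvest_juvenile"]).reset_index(drop=True)
    harvest = AgeAtHarvestData(
        study["year"], study["spring_harvest_juvenile"], study["spring_harvest_adult"],
        study["effort"], study["effort_se"])
    rt = study.dropna(subset=["rt_at_risk_juvenile"])
    tel = TelemetryData(
        np.concatenate([rt["year"], rt["year"]]),
        np.array(["juvenile"] * len(rt) + ["adult"] * len(rt), dtype=object),
        np.concatenate([rt["rt_at_risk_juvenile"], rt["rt_at_risk_adult"]]),
        np.concatenate([rt["rt_harvested_juvenile"], rt["rt_harvested_adult"]]),
    )
    removals = RemovalData(
        study["year"], study["spring_npr_juvenile"], study["spring_npr_adult"],
        study["fall_harvest_juvenile"], study["fall_harvest_adult"],
        poult_hen_ratio=study["poult_hen_ratio"], archer_index=study["archer_index"])
    ph = pd.Series(df["poult_hen_ratio"].to_numpy(), index=df["year"].to_numpy())
    ai = pd.Series(study["archer_index"].to_numpy(), index=study["year"].to_numpy())
    return TurkeyDataset(harvest, tel, removals, ph, ai)


def turkey_harvest_prob(c, f, nu=0.0):
    """Class-specific spring harvest probability ``1 - exp(-c f e^nu)``."""
    return harvest_probability(c, f, nu)


def interval_survival(s_base, delta=0.0, weeks=SUMMER_WEEKS):
    """Survival over one within-year interval: annual survival^(weeks/46).

    The 22-week summer (spring to fall harvest) and 24-week winter (fall
    harvest to next spring) intervals compose exactly to the annual rate.
    """
    if weeks not in (SUMMER_WEEKS, WINTER_WEEKS):
        raise ValueError(f"interval length must be {SUMMER_WEEKS} or {WINTER_WEEKS} weeks")
    return survival(s_base, delta) ** (weeks / _YEAR_WEEKS)


def expected_adults_next_year(J, A, spring_npr_juvenile, spring_npr_adult,
                              fall_harvest_adult, PJ, PA, s_base, delta=0.0):
    """Expected adults just before next spring's removals.

    ``J`` and ``A`` are abundances immediately prior to the spring removals of
    the current year.  Juveniles not removed in spring graduate to adults
    after the permitted harvest; fall juvenile removals never enter (poult
    production is not modeled).
    """
    sS = interval_survival(s_base, delta, SUMMER_WEEKS)
    sW = interval_survival(s_base, delta, WINTER_WEEKS)
    j_avail = J - spring_npr_juvenile
    a_avail = A - spring_npr_adult
    if j_avail < 0:
        raise ValueError("negative abundance after spring juvenile removals")
    if a_avail < 0:
        raise ValueError("negative abundance after spring adult removals")
    post_summer = (j_avail * (1.0 - PJ) + a_avail * (1.0 - PA)) * sS
    post_fall = post_summer - fall_harvest_adult
    if post_fall < 0:
        raise ValueError("negative abundance after the fall adult removal")
    return post_fall * sW


# ---------------------------------------------------------------------------
# fitting


def _turkey_packer(spec: TurkeyModelSpec):
    if spec.separate_vulnerability:
        names = ["s_base", "c_juvenile", "c_adult"]
        transforms = ["logit", "log", "log"]
        lowers = [-7.0, np.log(1e-6), np.log(1e-6)]
        uppers = [7.0, np.log(1e2), np.log(1e2)]
    else:
        names = ["s_base", "c_shared"]
        transforms = ["logit", "log"]
        lowers = [-7.0, np.log(1e-6)]
        uppers = [7.0, np.log(1e2)]
    for flag, nm in (("vuln_juvenile", "sigma_c_juvenile"),
                     ("vuln_adult", "sigma_c_adult"),
                     ("survival", "sigma_s")):
        if flag in spec.re_structure:
            names.append(nm); transforms.append("log")
            lowers.append(np.log(1e-3)); uppers.append(np.log(3.0))
    return _Packer(names, transforms, lowers, uppers)


def _apply_turkey(engine: TurkeyEngine, packer: _Packer, spec: TurkeyModelSpec, x):
    nat = dict(zip(packer.names, packer.to_natural(x)))
    if spec.separate_vulnerability:
        cJ, cA = nat["c_juvenile"], nat["c_adult"]
    else:
        cJ = cA = nat["c_shared"]
    engine.set_params(nat["s_base"], cJ, cA,
                      nat.get("sigma_c_juvenile"), nat.get("sigma_c_adult"),
                      nat.get("sigma_s"))
    return nat


def _apply_turkey_batched(engine: TurkeyEngine, packer: _Packer,
                          spec: TurkeyModelSpec, X):
    nat = packer.to_natural_matrix(X)
    cols = {name: nat[:, i][:, None, None] for i, name in enumerate(packer.names)}
    if spec.separate_vulnerability:
        cJ, cA = cols["c_juvenile"], cols["c_adult"]
    else:
        cJ = cA = cols["c_shared"]
    engine.set_params(cols["s_base"], cJ, cA,
                      cols.get("sigma_c_juvenile"), cols.get("sigma_c_adult"),
                      cols.get("sigma_s"))


def fit_turkey(dataset: TurkeyDataset, spec: TurkeyModelSpec | None = None,
               init: dict | None = None, compute_uncertainty: bool = True,
               grouping: str = "pooled") -> FitResult:
    """Fit the two-season turkey model with the EM-style Horvitz-Thompson loop."""
    spec = spec or TurkeyModelSpec()
    data, telemetry, removals = dataset.harvest, dataset.telemetry, dataset.removals
    engine = TurkeyEngine(data, telemetry, removals, re_structure=spec.re_structure,
                          grouping=grouping)
    packer = _turkey_packer(spec)

    fbar = float(np.mean(data.effort))
    defaults = {"s_base": 0.5, "c_juvenile": -np.log(0.9) / fbar,
                "c_adult": -np.log(0.7) / fbar, "c_shared": -np.log(0.7) / fbar,
                "sigma_c_juvenile": 0.1, "sigma_c_adult": 0.1, "sigma_s": 0.1}
    if init:
        defaults.update(init)
    x = packer.to_x([defaults[n] for n in packer.names])
    objective = MarginalObjective(
        engine, lambda xv: _apply_turkey(engine, packer, spec, xv), engine.n_re,
        apply_x_batched=lambda X: _apply_turkey_batched(engine, packer, spec, X))

    # Horvitz-Thompson plug-ins are substituted at the current parameters
    # inside the engine, so a single maximization suffices.
    opt = _maximize(objective, x, packer.bounds, maxiter=500)
    x = opt.x
    converged = bool(opt.success)
    n_outer = 1

    nat = _apply_turkey(engine, packer, spec, x)
    u_hat = objective.eb_mode(x)
    neg_marginal = objective(x)
    delta_hat, nuJ_hat, nuA_hat = engine.split_effects(u_hat)
    PJ, PA = engine.harvest_prob(nuJ_hat, nuA_hat)
    s_hat = survival(nat["s_base"], delta_hat)

    Nspring = (data.juvenile_harvest / np.maximum(PJ, 1e-8)
               + data.adult_harvest / np.maximum(PA, 1e-8)
               + engine.RJs + engine.RAs)
    params = dict(zip(packer.names, packer.to_natural(x)))
    aic = 2.0 * len(packer.names) + 2.0 * neg_marginal

    if compute_uncertainty:
        se, ab_se = _turkey_uncertainty(engine, packer, spec, data, objective, x, PJ, PA)
    else:
        se, ab_se = {}, np.full(engine.Y, np.nan)
    abundance = pd.DataFrame({
        "year": data.years, "estimate": Nspring, "se": ab_se,
        "lo95": Nspring - _Z95 * ab_se, "hi95": Nspring + _Z95 * ab_se,
    })
    return FitResult(
        params=params, se=se,
        eb_effects={"delta": delta_hat, "nu_juvenile": nuJ_hat, "nu_adult": nuA_hat},
        loglik=-neg_marginal, aic=aic, abundance=abundance,
        converged=converged, n_outer_iterations=n_outer, spec=spec,
        harvest_prob=np.vstack([PJ, PA]), survival_series=s_hat,
        extra={"engine": engine, "packer": packer, "x": x, "objective": objective,
               "PJ": PJ, "PA": PA, "dataset": dataset},
    )


def _turkey_uncertainty(engine, packer, spec, data, objective, x_hat, PJ_hat, PA_hat):
    at_bound = packer.at_bound(x_hat)
    idx = np.where(~at_bound)[0]
    theta_hat = packer.to_natural(x_hat)

    def obj_nat_free(tf):
        theta = theta_hat.copy()
        theta[idx] = tf
        return objective(packer.to_x(theta))

    se = {n: np.nan for n in packer.names}
    cov = None
    if len(idx):
        try:
            H = fd_hessian_scalar(obj_nat_free, theta_hat[idx], rel_step=1e-4)
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            for j, i in enumerate(idx):
                se[packer.names[i]] = float(np.sqrt(d[j])) if d[j] > 0 else np.nan
        except np.linalg.LinAlgError:
            log.warning("singular Hessian: turkey parameter SEs unavailable")
    objective(x_hat)
    if cov is None:
        return se, np.full(engine.Y, np.nan)

    def nhat_of(tf):
        theta = theta_hat.copy()
        theta[idx] = tf
        u = objective.eb_mode(packer.to_x(theta))
        _, nuJ, nuA = engine.split_effects(u)
        PJ, PA = engine.harvest_prob(nuJ, nuA)
        return (data.juvenile_harvest / np.maximum(PJ, 1e-8)
                + data.adult_harvest / np.maximum(PA, 1e-8) + engine.RJs + engine.RAs)

    J = np.empty((engine.Y, len(idx)))
    for j in range(len(idx)):
        h = 1e-4 * max(1.0, abs(theta_hat[idx[j]]))
        e = np.zeros(len(idx)); e[j] = h
        J[:, j] = (nhat_of(theta_hat[idx] + e) - nhat_of(theta_hat[idx] - e)) / (2 * h)
    objective(x_hat)
    var = np.einsum("ij,jk,ik->i", J, cov, J)
    var = var + data.juvenile_harvest * (1 - PJ_hat) / np.maximum(PJ_hat, 1e-8) ** 2 \
        + data.adult_harvest * (1 - PA_hat) / np.maximum(PA_hat, 1e-8) ** 2
    # prediction variance of the empirical Bayes vulnerability effects
    lap = objective.last_laplace
    if engine.n_re and lap is not None:
        try:
            Hinv = np.linalg.pinv(0.5 * (lap.hessian + lap.hessian.T))
            from ._engine import _alpha
            Y = engine.Y
            g = np.zeros((Y, engine.n_re))
            off = Y if engine.has_delta else 0
            if engine.has_nuJ:
                nuJ = lap.mode[off:off + Y]
                aJ = engine.cJ * engine.f * np.exp(nuJ)
                alJ = _alpha(aJ, PJ_hat)
                g[np.arange(Y), off + np.arange(Y)] = \
                    -data.juvenile_harvest * alJ / np.maximum(PJ_hat, 1e-8)
                off += Y
            if engine.has_nuA:
                nuA = lap.mode[off:off + Y]
                aA = engine.cA * engine.f * np.exp(nuA)
                alA = _alpha(aA, PA_hat)
                g[np.arange(Y), off + np.arange(Y)] = \
                    -data.adult_harvest * alA / np.maximum(PA_hat, 1e-8)
            var = var + np.maximum(np.einsum("ij,jk,ik->i", g, Hinv, g), 0.0)
        except np.linalg.LinAlgError:
            pass
    return se, np.sqrt(np.maximum(var, 0.0))


# ---------------------------------------------------------------------------
# derived quantities and model selection


def spring_abundance(fit_result: FitResult, data: AgeAtHarvestData | None = None,
                     removals: RemovalData | None = None) -> pd.Series:
    """Total spring abundance: HT-scaled harvests plus spring NPR removals."""
    ab = fit_result.abundance
    return pd.Series(ab["estimate"].to_numpy(), index=ab["year"].to_numpy())


def juvenile_spring_abundance(fit_result: FitResult) -> pd.Series:
    """Spring juvenile abundance: x_J / P_J plus spring juvenile NPR."""
    engine = fit_result.extra["engine"]
    PJ = fit_result.extra["PJ"]
    est = engine.xJ / np.maximum(PJ, 1e-8) + engine.RJs
    return pd.Series(est, index=engine.years)


def poult_hen_comparison(fit_result: FitResult, poult_hen: pd.Series) -> float:
    """Correlation of juvenile spring abundance with last year's poult-hen ratio.

    The productivity survey observes poults at 1-3 months; those birds appear
    as one-year-old spring juveniles the following year, so the ratio is
    advanced one year.  Returns the Pearson correlation (NaN when either
    series is constant).
    """
    juv = juvenile_spring_abundance(fit_result)
    years = juv.index.to_numpy()
    try:
        ratio = poult_hen.loc[years - 1].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError("poult-hen ratios must cover the year before each "
                         "reconstruction year") from exc
    j = juv.to_numpy()
    if np.std(ratio) == 0 or np.std(j) == 0:
        return float("nan")
    return float(np.corrcoef(j, ratio)[0, 1])


def mixture_chi2_pvalue(stat: float) -> float:
    """P-value from the 50:50 chi2_0 : chi2_1 mixture for a boundary LRT.

    Used when testing a variance component against zero; at statistic 0 the
    p-value is 1 by convention (half the mass is a point mass at zero).
    """
    if stat < 0:
        raise ValueError("likelihood ratio statistic must be non-negative")
    if stat == 0:
        return 1.0
    return float(0.5 * chi2.sf(stat, df=1))


def boundary_lrt(full: FitResult, reduced: FitResult) -> dict:
    """Likelihood ratio test of one variance component on the boundary."""
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return {"statistic": stat, "p_value": mixture_chi2_pvalue(stat)}


def model_selection(dataset: TurkeyDataset, candidates=None,
                    **fit_kwargs) -> pd.DataFrame:
    """Fit candidate turkey model structures and rank them by AIC.

    Unconverged candidates are excluded (with a note in the ``converged``
    column).  Boundary tests of individual variance components should use
    :func:`boundary_lrt` on nested pairs.
    """
    if candidates is None:
        candidates = [
            TurkeyModelSpec(separate_vulnerability=True,
                            re_structure=("vuln_juvenile", "vuln_adult")),
            TurkeyModelSpec(separate_vulnerability=True,
                            re_structure=("vuln_juvenile", "vuln_adult", "survival")),
            TurkeyModelSpec(separate_vulnerability=False,
                            re_structure=("vuln_juvenile", "vuln_adult")),
        ]
    rows = []
    for cand in candidates:
        fit_kwargs.setdefault("compute_uncertainty", False)
        res = fit_turkey(dataset, cand, **fit_kwargs)
        rows.append({
            "separate_vulnerability": cand.separate_vulnerability,
            "random_effects": "+".join(cand.re_structure) or "none",
            "k": len(res.params),
            "loglik": res.loglik,
            "aic": res.aic,
            "converged": res.converged,
        })
    df = pd.DataFrame(rows)
    ok = df[df["converged"]]
    df["delta_aic"] = df["aic"] - (ok["aic"].min() if len(ok) else np.nan)
    return df.sort_values("aic").reset_index(drop=True)
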