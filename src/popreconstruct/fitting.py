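"""Mixed-effects model fitting for two-age-class population reconstruction.

Random-effects (RE) models maximize the Laplace-approximated marginal
likelihood over the fixed effects; fixed-effects (FE) models maximize the
joint likelihood directly.  Horvitz-Thompson (HT) models substitute the
plug-in entry abundances x/P at the current parameters inside the likelihood;
the auxiliary catch-effort abundance, when enabled, is instead plugged in as
data and refreshed in an EM-style outer loop until the total abundance
estimate stabilizes.  Absolute-abundance (AA) models estimate the initial
cohort abundances as free parameters in a single maximization.

Standard errors come from the inverse Hessian of the (marginal or joint)
negative log-likelihood; annual abundance uncertainty adds the second-stage
Horvitz-Thompson binomial component ``sum_cells x (1-P)/P^2`` to the
delta-method variance of the abundance as a function of the fixed effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from ._engine import SENTINEL, TwoClassEngine, _binom_const
from .data import AgeAtHarvestData, ModelSpec, TelemetryData
from .laplace import fd_hessian_scalar, laplace_marginal_negloglik

__all__ = [
    "FitResult",
    "fit",
    "joint_negloglik",
    "standard_errors",
    "abundance_uncertainty",
    "fisher_se",
]

log = logging.getLogger(__name__)

_Z95 = 1.959963984540054


@dataclass
class FitResult:
    """Maximum likelihood fit of a population reconstruction model."""

    params: dict
    se: dict
    eb_effects: dict
    loglik: float
    aic: float
    abundance: pd.DataFrame
    converged: bool
    n_outer_iterations: int
    spec: object = None
    harvest_prob: np.ndarray | None = None       # P-hat per year (at EB effects)
    survival_series: np.ndarray | None = None    # s-hat per year (at EB effects)
    extra: dict = field(default_factory=dict)


def standard_errors(fit_result: FitResult) -> dict:
    """Per-parameter standard errors (sqrt of inverse-Hessian diagonal)."""
    return fit_result.se


def abundance_uncertainty(fit_result: FitResult) -> pd.DataFrame:
    """Annual abundance with SE and symmetric 95% confidence limits."""
    return fit_result.abundance


def fisher_se(negloglik_fn, theta, rel_step=1e-4):
    """SEs from the inverse Hessian of a scalar negative log-likelihood."""
    H = fd_hessian_scalar(negloglik_fn, np.asarray(theta, dtype=float), rel_step)
    cov = np.linalg.inv(H)
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)


# ---------------------------------------------------------------------------
# parameter packing


class _Packer:
    """Map between named natural parameters and a transformed real vector."""

    def __init__(self, names, transforms, lowers, uppers):
        self.names = list(names)
        self.transforms = list(transforms)  # 'logit' or 'log'
        self.bounds = [(lo, hi) for lo, hi in zip(lowers, uppers)]

    def to_x(self, values):
        x = np.empty(len(self.names))
        for i, (v, t) in enumerate(zip(values, self.transforms)):
            x[i] = logit(v) if t == "logit" else np.log(v)
        return x

    def to_natural(self, x):
        out = np.empty(len(self.names))
        for i, t in enumerate(self.transforms):
            out[i] = expit(x[i]) if t == "logit" else np.exp(x[i])
        return out

    def to_natural_matrix(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        for i, t in enumerate(self.transforms):
            out[:, i] = expit(X[:, i]) if t == "logit" else np.exp(X[:, i])
        return out

    def at_bound(self, x, tol=1e-6):
        return np.array([
            (lo is not None and xi <= lo + tol) or (hi is not None and xi >= hi - tol)
            for xi, (lo, hi) in zip(x, self.bounds)
        ])


def _fd_jac(fun, x, h=1e-5):
    g = np.empty_like(x)
    for i in range(len(x)):
        hi = h * max(1.0, abs(x[i]))
        e = np.zeros_like(x)
        e[i] = hi
        g[i] = (fun(x + e) - fun(x - e)) / (2.0 * hi)
    return g


_LOG_2PI = float(np.log(2.0 * np.pi))


class MarginalObjective:
    """Transformed-scale negative (marginal) log-likelihood with warm starts.

    When a batched parameter setter is available, the finite-difference
    gradient over the fixed effects is evaluated in a few vectorized passes
    instead of one full inner optimization per perturbed point: each
    perturbation's conditional mode is obtained by a single Newton step from
    the central mode (accurate to second order in the step size), after which
    the joint likelihood and the Hessian log-determinant are re-evaluated
    there.  Residual O(h^2) errors are symmetric and cancel in the central
    differences.
    """

    def __init__(self, engine, apply_x, n_re, apply_x_batched=None):
        self.engine = engine
        self.apply_x = apply_x  # callable: transformed vector -> engine state
        self.apply_x_batched = apply_x_batched
        self.n_re = n_re
        self.u_warm = None
        self.last_laplace = None

    def __call__(self, x):
        self.apply_x(np.asarray(x, dtype=float))
        if self.n_re == 0:
            v = float(np.asarray(self.engine.negloglik(np.zeros((1, 0))))[0])
            return v if np.isfinite(v) else SENTINEL
        res = laplace_marginal_negloglik(
            self.engine.negloglik, self.n_re, u0=self.u_warm, grad=self.engine.grad_u)
        if res.converged:
            self.u_warm = res.mode.copy()
        self.last_laplace = res
        return res.value if np.isfinite(res.value) else SENTINEL

    def eb_mode(self, x):
        self(x)
        if self.n_re == 0:
            return np.zeros(0)
        return self.last_laplace.mode

    def value_and_jac(self, x, h=1e-5):
        x = np.asarray(x, dtype=float)
        f0 = self(x)
        p = len(x)
        hs = h * np.maximum(1.0, np.abs(x))
        if self.apply_x_batched is None or not np.isfinite(f0) or f0 >= SENTINEL:
            return f0, _fd_jac(self, x, h)
        X = np.concatenate([x + np.diag(hs), x - np.diag(hs)], axis=0)  # (2p, p)
        B = 2 * p
        self.apply_x_batched(X)
        n = self.n_re
        ok = True
        if n:
            lap = self.last_laplace
            if lap is None or not lap.converged:
                self.apply_x(x)
                return f0, _fd_jac(self, x, h)
            u = lap.mode
            # one Newton step per perturbed parameter vector: u_k = u - H^-1 g_k
            g0 = self.engine.grad_u(np.broadcast_to(u, (B, 1, n)))[:, 0, :]
            try:
                steps = np.linalg.solve(lap.hessian, g0.T).T
            except np.linalg.LinAlgError:
                self.apply_x(x)
                return f0, _fd_jac(self, x, h)
            u_k = u[None, :] - steps  # (B, n)
            hu = 1e-4 * np.maximum(1.0, np.abs(u))
            stencil = np.concatenate([np.diag(hu), -np.diag(hu)], axis=0)  # (2n, n)
            pts = u_k[:, None, :] + stencil[None, :, :]  # (B, 2n, n)
            g = self.engine.grad_u(pts)
            Hd = (g[:, :n, :] - g[:, n:, :]) / (2.0 * hu)[None, :, None]
            H = 0.5 * (Hd + np.transpose(Hd, (0, 2, 1)))
            sign, logdet = np.linalg.slogdet(H)
            nll = self.engine.negloglik(u_k[:, None, :])[:, 0]
            vals = nll + 0.5 * logdet - 0.5 * n * _LOG_2PI
            ok = bool(np.all(sign > 0) and np.all(np.isfinite(vals)))
        else:
            vals = self.engine.negloglik(np.zeros((B, 1, 0)))[:, 0]
            ok = bool(np.all(np.isfinite(vals)))
        self.apply_x(x)  # restore the central state
        if not ok:
            return f0, _fd_jac(self, x, h)
        return f0, (vals[:p] - vals[p:]) / (2.0 * hs)


def _maximize(objective, x0, bounds, maxiter=200):
    res = minimize(objective.value_and_jac, x0, jac=True,
                   method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-5})
    return res


# ---------------------------------------------------------------------------
# two-class model fitting


def _build_packer(spec: ModelSpec, data: AgeAtHarvestData):
    names = ["s_base", "c"]
    transforms = ["logit", "log"]
    lowers = [-7.0, np.log(1e-6)]
    uppers = [7.0, np.log(1e3)]
    if spec.effects_mode == "RE":
        if "survival" in spec.re_structure:
            names.append("sigma_s"); transforms.append("log")
            lowers.append(np.log(1e-3)); uppers.append(np.log(3.0))
        if "vulnerability" in spec.re_structure:
            names.append("sigma_c"); transforms.append("log")
            lowers.append(np.log(1e-3)); uppers.append(np.log(3.0))
    if spec.abundance_mode == "AA":
        Y = data.n_years
        entry_harvest = np.concatenate([[data.adult_harvest[0]], data.juvenile_harvest])
        for j in range(Y + 1):
            names.append(f"n0_{j + 1}")
            transforms.append("log")
            lowers.append(np.log(max(entry_harvest[j], 0.5) + 1e-3))
            uppers.append(np.log(1e9))
    return names, transforms, lowers, uppers


def _apply_two_class(engine, packer, spec, x):
    nat = packer.to_natural(x)
    d = dict(zip(packer.names, nat))
    engine.set_params(d["s_base"], d["c"], d.get("sigma_s"), d.get("sigma_c"))
    if spec.abundance_mode == "AA":
        n0 = np.array([d[f"n0_{j + 1}"] for j in range(engine.Y + 1)])
        engine.set_abundances(n0[0], n0[1:], ntot=None)
    return d


def _apply_two_class_batched(engine, packer, spec, X):
    """Set engine parameters for a whole batch of perturbed vectors at once."""
    nat = packer.to_natural_matrix(X)
    cols = {name: nat[:, i] for i, name in enumerate(packer.names)}

    def b3(v):
        return v[:, None, None]

    engine.set_params(b3(cols["s_base"]), b3(cols["c"]),
                      b3(cols["sigma_s"]) if "sigma_s" in cols else None,
                      b3(cols["sigma_c"]) if "sigma_c" in cols else None)
    if spec.abundance_mode == "AA":
        n0 = np.stack([cols[f"n0_{j + 1}"] for j in range(engine.Y + 1)], axis=1)
        engine.set_abundances(n0[:, 0][:, None, None], n0[:, 1:][:, None, :], ntot=None)


def _aa_total_abundance(engine, u):
    """Model-implied total annual abundance for AA fits (juveniles + adults)."""
    u = np.zeros(engine.n_re) if u is None or not len(np.atleast_1d(u)) else u
    delta, _ = engine._split(np.atleast_2d(np.asarray(u, dtype=float)))
    s = engine.survival_series(np.asarray(delta).reshape(-1))
    return engine.aa_total_abundance(s)


def fit(spec: ModelSpec, data: AgeAtHarvestData, telemetry: TelemetryData,
        init: dict | None = None, em_tol: float = 1e-6, max_outer: int = 100,
        compute_uncertainty: bool = True, grouping: str = "pooled") -> FitResult:
    """Fit a reconstruction model; deterministic given data and initialization.

    HT models run the EM-style outer loop (plug-in abundances from Eq.-8-style
    Horvitz-Thompson estimates, refreshed with the empirical Bayes random
    effects) until the relative change in total abundance falls below
    ``em_tol`` or ``max_outer`` iterations; AA models are a single
    maximization over all parameters including the cohort entry abundances.
    """
    engine = TwoClassEngine(data, telemetry, spec, grouping=grouping)
    names, transforms, lowers, uppers = _build_packer(spec, data)
    packer = _Packer(names, transforms, lowers, uppers)

    fbar = float(np.mean(data.effort))
    defaults = {"s_base": 0.5, "c": -np.log(0.7) / fbar, "sigma_s": 0.1, "sigma_c": 0.1}
    P0 = 0.3
    entry_harvest = np.concatenate([[data.adult_harvest[0]], data.juvenile_harvest])
    for j in range(data.n_years + 1):
        defaults[f"n0_{j + 1}"] = max(entry_harvest[j], 0.5) / P0
    if init:
        defaults.update(init)
    x = packer.to_x([defaults[n] for n in names])
    for i, (lo, hi) in enumerate(packer.bounds):
        x[i] = np.clip(x[i], lo + 1e-9, hi - 1e-9)

    batched = None
    if not (spec.abundance_mode == "AA" and spec.effects_mode == "RE"
            and spec.include_catch_effort):
        batched = lambda X: _apply_two_class_batched(engine, packer, spec, X)
    objective = MarginalObjective(engine, lambda xv: _apply_two_class(engine, packer, spec, xv),
                                  engine.n_re, apply_x_batched=batched)

    # The cohort-entry Horvitz-Thompson plug-ins are substituted directly as
    # functions of the current parameters inside the engine; only the
    # catch-effort auxiliary keeps its abundance frozen as data, refreshed in
    # the EM-style outer loop below.
    em_active = spec.abundance_mode == "HT" and spec.include_catch_effort
    if em_active:
        engine.set_params(defaults["s_base"], defaults["c"],
                          defaults.get("sigma_s"), defaults.get("sigma_c"))
        engine.ntot = data.total_harvest / np.maximum(engine.harvest_prob(), 1e-8)
        engine._ce_const = float(np.sum(_binom_const(data.total_harvest, engine.ntot)))
    converged = False
    n_outer = 0
    prev_total = np.inf
    best_rel = np.inf
    stalled = 0
    maxiter = 500
    for n_outer in range(1, (max_outer if em_active else 1) + 1):
        opt = _maximize(objective, x, packer.bounds, maxiter=maxiter)
        x = opt.x
        u_hat = objective.eb_mode(x)
        if not em_active:
            converged = bool(opt.success)
            break
        delta_hat, nu_hat = engine._split(u_hat) if engine.n_re else (np.zeros(engine.Y),) * 2
        Phat = engine.harvest_prob(np.asarray(nu_hat).reshape(-1))
        ntot = data.total_harvest / np.maximum(Phat, 1e-8)
        total = float(np.sum(ntot))
        rel = abs(total - prev_total) / max(total, 1.0)
        engine.ntot = ntot
        engine._ce_const = float(np.sum(_binom_const(data.total_harvest, ntot)))
        log.debug("EM iteration %d: catch-effort N %.1f (rel change %.2e)",
                  n_outer, total, rel)
        if rel < em_tol:
            converged = bool(opt.success)
            break
        # the plug-in refreshes need not contract; stop once the relative
        # change stops improving rather than cycling to the iteration cap
        if rel < 0.9 * best_rel:
            best_rel = rel
            stalled = 0
        else:
            stalled += 1
            if stalled >= 5:
                log.warning("catch-effort EM stalled after %d iterations "
                            "(relative change %.2e)", n_outer, rel)
                break
        prev_total = total
        maxiter = 200
    else:
        converged = False

    # final state at the optimum
    nat = _apply_two_class(engine, packer, spec, x)
    u_hat = objective.eb_mode(x)
    neg_marginal = objective(x)
    if engine.n_re:
        delta_hat, nu_hat = engine._split(u_hat)
        delta_hat = np.asarray(delta_hat).reshape(-1)
        nu_hat = np.asarray(nu_hat).reshape(-1)
    else:
        delta_hat = np.zeros(engine.Y)
        nu_hat = np.zeros(engine.Y)
    Phat = engine.harvest_prob(nu_hat)
    shat = engine.survival_series(delta_hat)

    if spec.abundance_mode == "HT":
        Nhat = data.total_harvest / np.maximum(Phat, 1e-8)
    else:
        Nhat = _aa_total_abundance(engine, u_hat)

    params = {n: v for n, v in zip(names, packer.to_natural(x))}
    k = len(names)
    aic = 2.0 * k + 2.0 * neg_marginal

    se, abundance_se = _uncertainty(engine, packer, spec, data, objective, x, Nhat,
                                    Phat) if compute_uncertainty else ({}, np.full(engine.Y, np.nan))
    abundance = pd.DataFrame({
        "year": data.years,
        "estimate": Nhat,
        "se": abundance_se,
        "lo95": Nhat - _Z95 * abundance_se,
        "hi95": Nhat + _Z95 * abundance_se,
    })
    return FitResult(
        params=params, se=se,
        eb_effects={"delta": delta_hat, "nu": nu_hat},
        loglik=-neg_marginal, aic=aic, abundance=abundance,
        converged=converged, n_outer_iterations=n_outer, spec=spec,
        harvest_prob=Phat, survival_series=shat,
        extra={"engine": engine, "packer": packer, "x": x, "objective": objective},
    )


def _uncertainty(engine, packer, spec, data, objective, x_hat, Nhat, Phat):
    """Inverse-Hessian parameter SEs and delta-method abundance SEs."""
    at_bound = packer.at_bound(x_hat)
    free = ~at_bound
    idx = np.where(free)[0]
    theta_hat = packer.to_natural(x_hat)

    def obj_nat_free(theta_free):
        theta = theta_hat.copy()
        theta[idx] = theta_free
        return objective(packer.to_x(theta))

    se = {n: np.nan for n in packer.names}
    cov = None
    if len(idx):
        try:
            H = fd_hessian_scalar(obj_nat_free, theta_hat[idx], rel_step=1e-4)
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.any(d < 0):
                log.warning("non-positive-definite Hessian: some SEs unavailable")
            for j, i in enumerate(idx):
                se[packer.names[i]] = float(np.sqrt(d[j])) if d[j] > 0 else np.nan
        except np.linalg.LinAlgError:
            log.warning("singular Hessian: parameter SEs unavailable")
    # restore optimum state
    objective(x_hat)

    Y = engine.Y
    if cov is None:
        return se, np.full(Y, np.nan)

    def nhat_of(theta_free):
        theta = theta_hat.copy()
        theta[idx] = theta_free
        xv = packer.to_x(theta)
        u = objective.eb_mode(xv)
        if spec.abundance_mode == "HT":
            if engine.n_re:
                _, nu = engine._split(u)
                nu = np.asarray(nu).reshape(-1)
            else:
                nu = np.zeros(Y)
            P = engine.harvest_prob(nu)
            return data.total_harvest / np.maximum(P, 1e-8)
        return _aa_total_abundance(engine, u)

    J = np.empty((Y, len(idx)))
    for j in range(len(idx)):
        h = 1e-4 * max(1.0, abs(theta_hat[idx[j]]))
        e = np.zeros(len(idx)); e[j] = h
        J[:, j] = (nhat_of(theta_hat[idx] + e) - nhat_of(theta_hat[idx] - e)) / (2 * h)
    objective(x_hat)
    var = np.einsum("ij,jk,ik->i", J, cov, J)
    if spec.abundance_mode == "HT":
        # second-stage Horvitz-Thompson binomial component
        var = var + data.total_harvest * (1.0 - Phat) / np.maximum(Phat, 1e-8) ** 2
        # conditional spread of the predicted vulnerability effects: the HT
        # estimator divides by P(nu-hat), and nu-hat is itself uncertain
        lap = objective.last_laplace
        if engine.n_re and lap is not None:
            try:
                Hinv = np.linalg.pinv(0.5 * (lap.hessian + lap.hessian.T))
                _, nu_hat = engine._split(lap.mode)
                nu_hat = np.asarray(nu_hat).reshape(-1)
                a = engine.c * engine.f * np.exp(nu_hat)
                from ._engine import _alpha
                al = _alpha(a, Phat)
                gnu = -data.total_harvest * al / np.maximum(Phat, 1e-8)
                off = Y if engine.has_delta else 0
                dHi = np.diag(Hinv)[off:off + Y] if engine.has_nu else np.zeros(Y)
                var = var + gnu**2 * np.maximum(dHi, 0.0)
            except np.linalg.LinAlgError:
                pass
    var = np.maximum(var, 0.0)
    return se, np.sqrt(var)


# ---------------------------------------------------------------------------
# spec-level joint likelihood evaluation


def joint_negloglik(params, data: AgeAtHarvestData, telemetry: TelemetryData,
                    spec: ModelSpec) -> float:
    """Negative joint log-likelihood at a given parameter state.

    For HT models the entry abundances are the Horvitz-Thompson plug-ins
    implied by the state's own harvest probabilities; for AA models they are
    ``params.n0``.  The value is the sum of the conditional age-at-harvest
    component, the edge-cohort binomials, telemetry, the optional catch-effort
    component and (RE models) the random-effect normal penalties.
    """
    engine = TwoClassEngine(data, telemetry, spec)
    delta, nu = params.effects(data.n_years)
    engine.set_params(params.s_base, params.c_base,
                      params.sigma_s if spec.effects_mode == "RE" else None,
                      params.sigma_c if spec.effects_mode == "RE" else None)
    if spec.abundance_mode == "AA":
        if params.n0 is None:
            raise ValueError("AA models require initial cohort abundances n0")
        engine.set_abundances(params.n0[0], params.n0[1:])
    elif spec.include_catch_effort:
        # catch-effort abundance plugged in as data (the EM-form auxiliary)
        P = engine.harvest_prob(nu)
        engine.ntot = data.total_harvest / np.maximum(P, 1e-8)
        engine._ce_const = float(np.sum(_binom_const(data.total_harvest, engine.ntot)))
    u = []
    if engine.has_delta:
        u.append(delta)
    if engine.has_nu:
        u.append(nu)
    uvec = np.concatenate(u) if u else np.zeros(0)
    return float(np.asarray(engine.negloglik(uvec[None]))[0])
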