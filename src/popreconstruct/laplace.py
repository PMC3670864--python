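"""Laplace approximation of marginal likelihoods over random effects.

The marginal likelihood integrates the joint likelihood over the temporal
random effects.  With ``g(u)`` the *negative* joint log-likelihood as a
function of the random-effect vector ``u`` (fixed effects held constant), the
approximation is

    -log L_marginal  ~=  g(u*) + 0.5 log det H(u*) - (n/2) log(2 pi)

where ``u*`` is the conditional mode (the empirical Bayes prediction of the
random effects) and ``H`` the Hessian of ``g`` at the mode.  The approximation
is exact whenever ``g`` is quadratic in ``u`` (linear-Gaussian inner problems).

The inner mode is found by damped Newton iterations; Hessians are central
finite differences of the (analytic or finite-difference) gradient.  Objective
callables must accept batched inputs of shape ``(..., n)`` and return
``(...,)`` so the finite-difference stencils evaluate in one vectorized call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LaplaceResult",
    "fd_gradient",
    "fd_hessian_from_grad",
    "fd_hessian_scalar",
    "laplace_marginal_negloglik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def fd_gradient(f, u, rel_step=1e-6):
    """Central-difference gradient of a batched scalar function at ``u``."""
    u = np.asarray(u, dtype=float)
    n = u.shape[-1]
    h = rel_step * np.maximum(1.0, np.abs(u))
    pts = np.concatenate([u + np.diag(h), u - np.diag(h)], axis=0)  # (2n, n)
    vals = np.asarray(f(pts))
    return (vals[:n] - vals[n:]) / (2.0 * h)


def fd_hessian_from_grad(grad, u, rel_step=1e-4):
    """Symmetrized central-difference Hessian from a batched gradient."""
    u = np.asarray(u, dtype=float)
    n = u.shape[-1]
    h = rel_step * np.maximum(1.0, np.abs(u))
    pts = np.concatenate([u + np.diag(h), u - np.diag(h)], axis=0)
    g = np.asarray(grad(pts))  # (2n, n)
    H = (g[:n] - g[n:]) / (2.0 * h)[:, None]
    return 0.5 * (H + H.T)


def fd_hessian_scalar(f, x, rel_step=1e-4):
    """Dense Hessian of a scalar function by central second differences.

    Used for inverse-Hessian standard errors of the (small) fixed-effect
    parameter vector, where ``f`` is typically itself a Laplace marginal and
    only supports one point per call.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    H = np.empty((n, n))
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _chol_with_ridge(H):
    """Cholesky factor of H, adding an escalating ridge if not positive definite."""
    n = H.shape[0]
    scale = max(np.abs(np.diag(H)).max(), 1e-12)
    ridge = 0.0
    for k in range(12):
        try:
            L = np.linalg.cholesky(H + ridge * np.eye(n))
            return L, ridge
        except np.linalg.LinAlgError:
            ridge = scale * 10.0 ** (k - 8)
    raise np.linalg.LinAlgError("Hessian could not be regularized")


@dataclass
class LaplaceResult:
    value: float          # approximate marginal negative log-likelihood
    mode: np.ndarray      # conditional mode of the random effects (empirical Bayes)
    hessian: np.ndarray   # Hessian of the inner objective at the mode
    converged: bool
    n_iter: int
    hessian_pd: bool = True


def laplace_marginal_negloglik(negloglik, n_re, u0=None, grad=None,
                               gtol=1e-9, max_iter=100) -> LaplaceResult:
    """Laplace-approximate the marginal negative log-likelihood.

    Parameters
    ----------
    negloglik : callable accepting ``(..., n_re)`` arrays, returning ``(...,)``;
        the negative joint log-likelihood as a function of the random effects.
    n_re : random-effect dimension; 0 returns ``negloglik([])`` unchanged.
    u0 : warm start for the inner Newton iterations (defaults to zeros).
    grad : optional batched analytic gradient; finite differences otherwise.
    """
    if n_re == 0:
        val = float(np.asarray(negloglik(np.zeros((1, 0))))[0])
        return LaplaceResult(val, np.zeros(0), np.zeros((0, 0)), True, 0)

    g = grad if grad is not None else (lambda u: _batched_fd_grad(negloglik, u))
    u = np.zeros(n_re) if u0 is None else np.array(u0, dtype=float)
    f0 = float(negloglik(u[None])[0])
    if not np.isfinite(f0) or f0 >= 1e9:
        u = np.zeros(n_re)
        f0 = float(negloglik(u[None])[0])
    if not np.isfinite(f0) or f0 >= 1e9:
        # degenerate parameter region (sentinel likelihood): report it as such
        # so the outer optimizer backtracks instead of polishing garbage
        return LaplaceResult(f0, u, np.eye(n_re), False, 0, False)
    tol = gtol * (1.0 + abs(f0))
    converged = False
    it = 0
    step_tol = 1e-8
    for it in range(1, max_iter + 1):
        gr = np.asarray(g(u[None]))[0]
        if not np.all(np.isfinite(gr)):
            break
        if np.max(np.abs(gr)) < tol:
            converged = True
            break
        H = fd_hessian_from_grad(g, u)
        if not np.all(np.isfinite(H)):
            break
        try:
            L, _ = _chol_with_ridge(H)
        except np.linalg.LinAlgError:
            break
        step = np.linalg.solve(L.T, np.linalg.solve(L, gr))
        # convergence in parameter space: with a stiff penalty (sigma at its
        # lower bound) the raw gradient norm cannot reach tol at double
        # precision, but a sub-1e-8 Newton step changes the marginal value by
        # O(step^2 * curvature), far below optimizer resolution
        if np.max(np.abs(step)) < step_tol * (1.0 + np.max(np.abs(u))):
            u_new = u - step
            f_new = float(negloglik(u_new[None])[0])
            if np.isfinite(f_new) and f_new <= f0:
                u, f0 = u_new, f_new
            converged = True
            break
        # backtracking line search on the inner objective
        t = 1.0
        accepted = False
        descent = float(gr @ step)
        for _ in range(30):
            u_new = u - t * step
            f_new = float(negloglik(u_new[None])[0])
            if np.isfinite(f_new) and f_new <= f0 - 1e-4 * t * descent:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            converged = np.max(np.abs(gr)) < 1e3 * tol or np.max(np.abs(step)) < 1e-6
            break
        if abs(f0 - f_new) <= 1e-13 * (1.0 + abs(f0)) and np.max(np.abs(gr)) < 1e3 * tol:
            u, f0 = u_new, f_new
            converged = True
            break
        u, f0 = u_new, f_new

    if not converged:
        gmax = float(np.max(np.abs(np.asarray(g(u[None]))[0])))
        if f0 >= 1e9 or gmax > 1e8:
            # sentinel plateau or wildly degenerate curvature: not worth polishing
            return LaplaceResult(max(f0, 1e9), u, np.eye(n_re), False, it, False)
        # fall back to a quasi-Newton search from the best point found
        from scipy.optimize import minimize
        res = minimize(lambda v: float(negloglik(v[None])[0]), u, method="BFGS",
                       jac=lambda v: np.asarray(g(v[None]))[0],
                       options={"maxiter": 100, "gtol": 10 * tol})
        if res.fun <= f0 or not np.isfinite(f0):
            u, f0 = res.x, float(res.fun)
        converged = bool(np.max(np.abs(np.asarray(g(u[None]))[0])) < 1e4 * tol)

    H = fd_hessian_from_grad(g, u)
    sign, logdet = np.linalg.slogdet(H)
    hessian_pd = bool(sign > 0)
    if not hessian_pd:
        L, ridge = _chol_with_ridge(0.5 * (H + H.T))
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    value = f0 + 0.5 * logdet - 0.5 * n_re * _LOG_2PI
    return LaplaceResult(float(value), u, H, converged and hessian_pd, it, hessian_pd)


def _batched_fd_grad(negloglik, u):
    """FD gradient that itself supports batched input (used when no analytic grad)."""
    u = np.asarray(u, dtype=float)
    squeeze = u.ndim == 1
    if squeeze:
        u = u[None]
    B, n = u.shape
    h = 1e-5 * np.maximum(1.0, np.abs(u))  # (B, n)
    eye = np.eye(n)
    # build the (B, 2n, n) central-difference perturbation stack
    pert = np.concatenate([
        u[:, None, :] + eye[None] * h[:, :, None],
        u[:, None, :] - eye[None] * h[:, :, None],
    ], axis=1)
    vals = np.asarray(negloglik(pert.reshape(B * 2 * n, n))).reshape(B, 2 * n)
    grad = (vals[:, :n] - vals[:, n:]) / (2.0 * h)
    return grad[0] if squeeze else grad
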