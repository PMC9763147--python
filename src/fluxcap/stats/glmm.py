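"""Gamma generalized linear mixed model with inverse link.

Model: y_ij ~ Gamma(shape k, mean mu_ij) with

    1 / mu_ij = eta_ij = x_ij' beta + u_i,    u_i ~ N(0, s2_u)

The marginal likelihood integrates the random intercepts out numerically.
The default is the Laplace approximation: for each group the integrand is
maximised over u_i by a damped Newton search (the negative log-integrand
is strictly convex on the feasible region eta > 0, which acts as a natural
barrier), and the curvature at the mode supplies the Gaussian correction.
Adaptive Gauss-Hermite quadrature (``method="agq"``, >= 9 nodes, centred
and scaled at the Laplace mode) is available as a verification route.

Fitting maximises the approximate marginal likelihood over
(beta, log k, log s_u) with BFGS (Nelder-Mead fallback); standard errors
come from the inverse observed information at the optimum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from ..errors import UsageError, ValidationError
from .model import GAMMA_INVERSE, MixedModelFit, ModelSpec, prepare

_BIG = 1e10


def _group_slices(gidx: np.ndarray, n_groups: int) -> list[np.ndarray]:
    return [np.flatnonzero(gidx == g) for g in range(n_groups)]


def _gamma_loglik(y: np.ndarray, eta: np.ndarray, k: float) -> float:
    """Sum of gamma log-densities with shape k and inverse-link eta = 1/mu."""
    return float(np.sum(k * np.log(k * eta) + (k - 1.0) * np.log(y)
                        - k * y * eta) - len(y) * gammaln(k))


def _mode(y: np.ndarray, a: np.ndarray, k: float, s2u: float,
          u0: float = 0.0) -> tuple[float, float, float] | None:
    """Mode of the per-group integrand over u.

    Minimises h(u) = -sum log f(y_j | eta_j = a_j + u) + u^2/(2 s2u)
    (the log-normalizer of the Gaussian prior is added by the caller).
    Returns (u_hat, h(u_hat), h''(u_hat)) or None if no feasible point.
    """
    lo = -np.min(a)          # feasibility: u > lo
    u = u0 if u0 > lo else lo + max(1.0, abs(lo)) * 1e-3

    def h(u: float) -> float:
        eta = a + u
        return (-np.sum(k * np.log(k * eta) - k * y * eta) + u * u / (2 * s2u))

    hu = h(u)
    for _ in range(100):
        eta = a + u
        g = -k * np.sum(1.0 / eta) + k * np.sum(y) + u / s2u
        H = k * np.sum(1.0 / eta ** 2) + 1.0 / s2u
        step = -g / H
        # damped step, kept strictly inside the feasible region
        new = u + step
        t = 1.0
        while new <= lo or h(new) > hu + 1e-12:
            t *= 0.5
            if t < 1e-12:
                break
            new = u + t * step
        if t < 1e-12:
            break
        u, hu = new, h(new)
        if abs(t * step) < 1e-11 * (1.0 + abs(u)):
            break
    eta = a + u
    if np.any(eta <= 0):
        return None
    H = k * np.sum(1.0 / eta ** 2) + 1.0 / s2u
    return u, hu, H


def _group_logmarg(y: np.ndarray, a: np.ndarray, k: float, s2u: float,
                   method: str, nodes: int, u0: float
                   ) -> tuple[float, float] | None:
    """Log marginal likelihood contribution of one group, and its u mode."""
    res = _mode(y, a, k, s2u, u0)
    if res is None:
        return None
    u_hat, h_min, H = res
    const = ((k - 1.0) * np.sum(np.log(y)) - len(y) * gammaln(k)
             - 0.5 * np.log(2.0 * np.pi * s2u))
    if method == "laplace":
        return const - h_min + 0.5 * np.log(2.0 * np.pi / H), u_hat
    # adaptive Gauss-Hermite centred at the Laplace mode
    z, w = np.polynomial.hermite.hermgauss(nodes)
    sd = 1.0 / np.sqrt(H)
    u_nodes = u_hat + np.sqrt(2.0) * sd * z
    vals = np.full(nodes, -np.inf)
    for i, u in enumerate(u_nodes):
        eta = a + u
        if np.any(eta <= 0):
            continue
        vals[i] = (np.sum(k * np.log(k * eta) - k * y * eta)
                   - u * u / (2.0 * s2u) + z[i] ** 2 + np.log(w[i]))
    return const + 0.5 * np.log(2.0) + np.log(sd) + logsumexp(vals), u_hat


def _neg_marginal(psi: np.ndarray, y_groups: list[np.ndarray],
                  X_groups: list[np.ndarray], method: str, nodes: int,
                  u_cache: np.ndarray) -> float:
    p = X_groups[0].shape[1]
    beta, log_k, log_su = psi[:p], psi[p], psi[p + 1]
    if log_k > 25 or log_su < -12:
        return _BIG
    k, s2u = np.exp(log_k), np.exp(2.0 * log_su)
    total = 0.0
    for g, (yg, Xg) in enumerate(zip(y_groups, X_groups)):
        a = Xg @ beta
        out = _group_logmarg(yg, a, k, s2u, method, nodes, u_cache[g])
        if out is None:
            return _BIG
        lm, u_hat = out
        u_cache[g] = u_hat
        total += lm
    if not np.isfinite(total):
        return _BIG
    return -total


def fit_gamma_glmm(data: pd.DataFrame, spec: ModelSpec,
                   method: str = "laplace", agq_nodes: int = 9
                   ) -> MixedModelFit:
    """ML fit of the gamma random-intercept GLMM (inverse link).

    ``method`` selects the marginal-likelihood approximation: ``"laplace"``
    (default) or ``"agq"`` with ``agq_nodes`` quadrature nodes.
    """
    if spec.family != GAMMA_INVERSE:
        raise UsageError(f"fit_gamma_glmm requires family {GAMMA_INVERSE!r}")
    if method not in ("laplace", "agq"):
        raise UsageError(f"unknown method {method!r}")
    if method == "agq" and agq_nodes < 3:
        raise UsageError("agq needs >=3 nodes")
    y, X, design, gidx, labels = prepare(data, spec)
    n_groups = len(labels)
    slices = _group_slices(gidx, n_groups)
    y_groups = [y[s] for s in slices]
    X_groups = [X[s] for s in slices]

    beta0, k0 = _glm_start(y, X)
    psi0 = np.concatenate([beta0, [np.log(k0)], [np.log(0.1 * abs(beta0[0]) + 1e-3)]])
    u_cache = np.zeros(n_groups)
    args = (y_groups, X_groups, method, agq_nodes, u_cache)

    if _neg_marginal(psi0, *args) >= _BIG:
        # shrink non-intercept effects until the inverse link is feasible
        for shrink in (0.5, 0.1, 0.0):
            trial = psi0.copy()
            trial[1:len(beta0)] *= shrink
            if _neg_marginal(trial, *args) < _BIG:
                psi0 = trial
                break

    res = minimize(_neg_marginal, psi0, args=args, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-10})
    res2 = minimize(_neg_marginal, res.x, args=args, method="BFGS",
                    options={"gtol": 1e-7, "maxiter": 500})
    best = res2 if res2.fun <= res.fun else res
    converged = bool(best.fun < _BIG and (res.success or res2.success))

    psi = best.x
    p = X.shape[1]
    beta, k, su = psi[:p], float(np.exp(psi[p])), float(np.exp(psi[p + 1]))
    ll = -float(best.fun)
    cov = _cov_from_hessian(psi, args, p)
    # final pass to refresh the per-group modes at the optimum
    _neg_marginal(psi, *args)
    return MixedModelFit(
        spec=spec, design=design, params=beta, cov_params=cov,
        random_intercept_variance=su ** 2, residual_dispersion=1.0 / k,
        log_likelihood=ll, n_obs=len(y), n_groups=n_groups,
        converged=converged,
        method=method if method == "laplace" else f"agq{agq_nodes}",
        group_labels=labels, group_effects=u_cache.copy(),
        _X=X, _y=y, _group_idx=gidx,
        warnings=[] if converged else ["optimizer_not_converged"])


def _glm_start(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Starting values from an ordinary gamma GLM (inverse link)."""
    import warnings

    import statsmodels.api as sm
    try:
        with warnings.catch_warnings():
            # statsmodels warns that the inverse link can leave the gamma
            # mean domain; feasibility is enforced by the outer optimizer
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=sm.families.Gamma(
                link=sm.families.links.InversePower())).fit()
        beta0 = np.asarray(glm.params, dtype=float)
        phi = float(glm.pearson_chi2) / max(glm.df_resid, 1)
        k0 = float(np.clip(1.0 / max(phi, 1e-8), 1e-2, 1e6))
        if np.all(X @ beta0 > 0):
            return beta0, k0
    except Exception:
        pass
    beta0 = np.zeros(X.shape[1])
    beta0[0] = 1.0 / float(np.mean(y))
    return beta0, 1.0 / max(float(np.var(y) / np.mean(y) ** 2), 1e-3)


def _cov_from_hessian(psi: np.ndarray, args: tuple, p: int) -> np.ndarray:
    """Fixed-effect covariance block from the numeric observed information."""
    m = len(psi)
    h = 1e-5 * np.maximum(np.abs(psi), 1.0)
    H = np.zeros((m, m))
    f = lambda x: _neg_marginal(x, *args)
    for i in range(m):
        for j in range(i, m):
            xpp, xpm, xmp, xmm = (psi.copy() for _ in range(4))
            xpp[i] += h[i]; xpp[j] += h[j]
            xpm[i] += h[i]; xpm[j] -= h[j]
            xmp[i] -= h[i]; xmp[j] += h[j]
            xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    try:
        cov_all = np.linalg.inv(H)
        cov = cov_all[:p, :p]
        if np.all(np.diag(cov) > 0):
            return cov
    except np.linalg.LinAlgError:
        pass
    # information matrix not positive definite (boundary variance): use the
    # beta block alone
    try:
        cov = np.linalg.inv(H[:p, :p])
        if np.all(np.diag(cov) > 0):
            return cov
    except np.linalg.LinAlgError:
        pass
    return np.full((p, p), np.nan)
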