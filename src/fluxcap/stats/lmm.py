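"""Random-intercept linear mixed model on log10-transformed responses.

The model is

    log10 y_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, s2_u),  e_ij ~ N(0, s2_e)

fitted by maximum likelihood (not REML) so that likelihood-ratio tests
between nested fixed-effect structures are valid.  For a single random
intercept the likelihood can be profiled down to a one-dimensional search
over the variance ratio lambda = s2_u / s2_e: given lambda, the GLS
estimate of beta and the residual variance are closed-form.  The boundary
lambda = 0 (no between-experiment variance) is evaluated explicitly and a
``singular_random_variance`` warning is attached when it is the optimum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ..errors import UsageError
from .model import GAUSSIAN_LOG10, MixedModelFit, ModelSpec, prepare

_LOG_2PI = np.log(2.0 * np.pi)


def _group_sums(X: np.ndarray, y: np.ndarray, gidx: np.ndarray, n_groups: int
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-group sums of X rows, y, and group sizes."""
    p = X.shape[1]
    sx = np.zeros((n_groups, p))
    sy = np.zeros(n_groups)
    np.add.at(sx, gidx, X)
    np.add.at(sy, gidx, y)
    ng = np.bincount(gidx, minlength=n_groups).astype(float)
    return sx, sy, ng


def _profile(lam: float, X: np.ndarray, y: np.ndarray, gidx: np.ndarray,
             sx: np.ndarray, sy: np.ndarray, ng: np.ndarray
             ) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Profile log-likelihood at variance ratio lambda.

    Returns (loglik, beta, s2_e, XtWX) with beta the GLS solution and s2_e
    the profiled ML residual variance.
    """
    n = len(y)
    c = lam / (1.0 + lam * ng)                       # per-group shrinkage
    XtWX = X.T @ X - (sx * c[:, None]).T @ sx
    XtWy = X.T @ y - (sx * c[:, None]).T @ sy
    beta = np.linalg.solve(XtWX, XtWy)
    r = y - X @ beta
    sr = sy - sx @ beta                               # per-group residual sums
    rss_w = float(r @ r - np.sum(c * sr ** 2))
    s2e = rss_w / n
    ll = -0.5 * (n * (_LOG_2PI + np.log(s2e)) + np.sum(np.log1p(lam * ng)) + n)
    return ll, beta, s2e, XtWX


def _fit_ml(y: np.ndarray, X: np.ndarray, gidx: np.ndarray, n_groups: int
            ) -> dict:
    sx, sy, ng = _group_sums(X, y, gidx, n_groups)

    def neg_ll(t: float) -> float:
        return -_profile(np.exp(t), X, y, gidx, sx, sy, ng)[0]

    res = minimize_scalar(neg_ll, bounds=(-18.0, 18.0), method="bounded",
                          options={"xatol": 1e-10})
    ll_opt = -res.fun
    ll0 = _profile(0.0, X, y, gidx, sx, sy, ng)[0]
    if ll0 >= ll_opt:
        lam = 0.0
    else:
        lam = float(np.exp(res.x))
    ll, beta, s2e, XtWX = _profile(lam, X, y, gidx, sx, sy, ng)
    cov = s2e * np.linalg.inv(XtWX)
    # BLUP of random intercepts: u_hat_g = c_g * sum of group residuals
    c = lam / (1.0 + lam * ng)
    sr = sy - sx @ beta
    u_hat = c * sr
    return {"lambda": lam, "loglik": ll, "beta": beta, "s2e": s2e,
            "s2u": lam * s2e, "cov": cov, "u_hat": u_hat,
            "sx": sx, "sy": sy, "ng": ng}


def fit_lmm_log10(data: pd.DataFrame, spec: ModelSpec) -> MixedModelFit:
    """ML fit of the random-intercept LMM on log10(response)."""
    if spec.family != GAUSSIAN_LOG10:
        raise UsageError(f"fit_lmm_log10 requires family {GAUSSIAN_LOG10!r}")
    y_raw, X, design, gidx, labels = prepare(data, spec)
    y = np.log10(y_raw)
    out = _fit_ml(y, X, gidx, len(labels))
    warnings = []
    if out["lambda"] == 0.0:
        warnings.append("singular_random_variance")
    return MixedModelFit(
        spec=spec, design=design, params=out["beta"], cov_params=out["cov"],
        random_intercept_variance=out["s2u"], residual_dispersion=out["s2e"],
        log_likelihood=out["loglik"], n_obs=len(y), n_groups=len(labels),
        converged=True, method="ml_profile",
        group_labels=labels, group_effects=out["u_hat"],
        _X=X, _y=y, _group_idx=gidx, warnings=warnings)


def _loglik_at(theta: np.ndarray, fit: MixedModelFit) -> float:
    """ML log-likelihood at variance parameters theta=(log s2_u, log s2_e).

    beta is profiled out (GLS at the implied lambda)."""
    s2u, s2e = np.exp(theta)
    lam = s2u / s2e
    X, y, gidx = fit._X, fit._y, fit._group_idx
    sx, sy, ng = _group_sums(X, y, gidx, fit.n_groups)
    n = len(y)
    c = lam / (1.0 + lam * ng)
    XtWX = X.T @ X - (sx * c[:, None]).T @ sx
    XtWy = X.T @ y - (sx * c[:, None]).T @ sy
    beta = np.linalg.solve(XtWX, XtWy)
    r = y - X @ beta
    sr = sy - sx @ beta
    rss_w = float(r @ r - np.sum(c * sr ** 2))
    return -0.5 * (n * (_LOG_2PI + np.log(s2e)) + np.sum(np.log1p(lam * ng))
                   + rss_w / s2e)


def _cvc_at(theta: np.ndarray, fit: MixedModelFit, contrast: np.ndarray) -> float:
    """c' Cov(beta) c at variance parameters theta (for Satterthwaite)."""
    s2u, s2e = np.exp(theta)
    lam = s2u / s2e
    X, gidx = fit._X, fit._group_idx
    sx, _, ng = _group_sums(X, fit._y, gidx, fit.n_groups)
    c = lam / (1.0 + lam * ng)
    XtWX = X.T @ X - (sx * c[:, None]).T @ sx
    v = np.linalg.solve(XtWX, contrast)
    return float(s2e * contrast @ v)


def satterthwaite_df(fit: MixedModelFit, contrast: np.ndarray) -> float:
    """Satterthwaite denominator df for a fixed-effect contrast.

    df = 2 f^2 / (g' H^-1 g) with f = c'Cov(beta)c as a function of the
    variance parameters, g its gradient, and H the observed information of
    the ML log-likelihood in those parameters (numeric derivatives).
    Falls back to the residual df when the variance estimate is singular.
    """
    resid_df = float(fit.n_obs - fit.design.n_params)
    s2u = fit.random_intercept_variance
    s2e = fit.residual_dispersion
    if s2u <= 0 or fit.n_groups < 3:
        return resid_df
    theta = np.log([s2u, s2e])
    h = 1e-4
    # numeric gradient of f and Hessian of -loglik
    f0 = _cvc_at(theta, fit, contrast)
    grad = np.zeros(2)
    for i in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        grad[i] = (_cvc_at(tp, fit, contrast) - _cvc_at(tm, fit, contrast)) / (2 * h)
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
            tpp[[i, j]] += h
            tmm[[i, j]] -= h
            tpm[i] += h
            tpm[j] -= h
            tmp[i] -= h
            tmp[j] += h
            val = -(_loglik_at(tpp, fit) - _loglik_at(tpm, fit)
                    - _loglik_at(tmp, fit) + _loglik_at(tmm, fit)) / (4 * h * h)
            H[i, j] = H[j, i] = val
    try:
        var_f = float(grad @ np.linalg.solve(H, grad))
    except np.linalg.LinAlgError:
        return resid_df
    if var_f <= 0:
        return resid_df
    df = 2.0 * f0 ** 2 / var_f
    return float(np.clip(df, 1.0, resid_df))
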