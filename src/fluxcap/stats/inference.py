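"""Likelihood-ratio tests, family choice, marginal-means contrasts, summaries.

These mirror the usual analysis of plate-assay panels: a quantity is
modelled with experiment as a random intercept, the fixed factor of
interest is tested by a likelihood-ratio test between nested ML fits, the
error family (Gaussian on log10 vs gamma with inverse link) is chosen by
residual diagnostics, and significant factors are followed up with
pairwise estimated-marginal-means contrasts with Tukey adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ..errors import UsageError, ValidationError
from .design import Design
from .glmm import fit_gamma_glmm
from .lmm import fit_lmm_log10, satterthwaite_df
from .model import GAMMA_INVERSE, GAUSSIAN_LOG10, MixedModelFit, ModelSpec

#: df treated as infinite (normal approximation) in contrast tests.
_Z_DF = 1e6


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test between nested ML fits."""

    term: str
    chi2: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.chi2 < 0 or not 0 <= self.p_value <= 1:
            raise ValidationError("invalid LRT result")


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise marginal-means comparison on the link scale."""

    pair: tuple[str, str]
    estimate_link_scale: float
    std_error: float
    statistic: float
    df: float
    p_unadjusted: float
    p_adjusted: float
    adjustment: str


@dataclass
class FamilyChoice:
    """Outcome of the residual-based family selection."""

    family: str
    shapiro_w: dict[str, float]
    fits: dict[str, MixedModelFit] = field(repr=False, default_factory=dict)


def fit_family(data: pd.DataFrame, spec: ModelSpec, **kwargs) -> MixedModelFit:
    """Dispatch to the fitter matching ``spec.family``."""
    if spec.family == GAUSSIAN_LOG10:
        return fit_lmm_log10(data, spec)
    return fit_gamma_glmm(data, spec, **kwargs)


def lrt(full: MixedModelFit, reduced: MixedModelFit) -> LRTResult:
    """LRT of nested fixed-effect structures (same data, same family, ML).

    chi2 is clamped at zero; df is the difference in fixed-effect counts.
    """
    if full.spec.family != reduced.spec.family:
        raise UsageError("LRT requires the same family in both fits")
    if full.spec.response != reduced.spec.response or full.n_obs != reduced.n_obs:
        raise UsageError("LRT requires the same data in both fits")
    full_cols = set(full.design.column_names)
    red_cols = set(reduced.design.column_names)
    if not red_cols <= full_cols:
        raise UsageError(
            f"reduced model is not nested in full model "
            f"(extra terms: {sorted(red_cols - full_cols)})")
    df = full.design.n_params - reduced.design.n_params
    chi2 = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    term = "+".join(sorted(set(full.spec.fixed) - set(reduced.spec.fixed))) or "(none)"
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(term=term, chi2=chi2, df=df, p_value=p)


def choose_family(data: pd.DataFrame, spec: ModelSpec) -> FamilyChoice:
    """Fit both candidate families and keep the one with more normal residuals.

    The concrete criterion is the Shapiro-Wilk W statistic of the
    conditional quantile (Dunn-Smyth) residuals, which are standard normal
    under the correct family and hence comparable across families (raw
    Pearson residuals are intrinsically skewed under a gamma model even
    when it is correct). Higher W wins; exact ties break to the
    Gaussian/log10 family. Both fits and both statistics are returned so
    the decision is auditable.
    """
    fits: dict[str, MixedModelFit] = {}
    ws: dict[str, float] = {}
    for family in (GAUSSIAN_LOG10, GAMMA_INVERSE):
        fit = fit_family(data, spec.with_family(family))
        if fit.converged:
            fits[family] = fit
            ws[family] = float(sps.shapiro(fit.quantile_residuals()).statistic)
    if not fits:
        raise ValidationError("no candidate family converged")
    if len(fits) == 1:
        family = next(iter(fits))
    else:
        family = (GAUSSIAN_LOG10 if ws[GAUSSIAN_LOG10] >= ws[GAMMA_INVERSE]
                  else GAMMA_INVERSE)
    return FamilyChoice(family=family, shapiro_w=ws, fits=fits)


def _marginal_mean_rows(design: Design, factor: str) -> dict[str, np.ndarray]:
    """Link-scale marginal-mean contrast vector per level of ``factor``.

    Levels of the other factors are averaged with equal weights.
    """
    grid = design.grid()
    Xg = design.matrix(grid)
    out = {}
    for level in design.levels[factor]:
        mask = (grid[factor].astype(str) == level).to_numpy()
        out[level] = Xg[mask].mean(axis=0)
    return out


def emm_contrasts(fit: MixedModelFit, factor: str,
                  adjustment: str = "tukey") -> list[ContrastResult]:
    """All pairwise estimated-marginal-means contrasts for one factor.

    Marginal means are computed on the link scale with equal weights over
    the other factors.  Denominator df: Satterthwaite for the Gaussian
    family, normal approximation for the gamma family.  ``adjustment`` is
    ``"tukey"`` (studentized-range, the default) or ``"none"``.
    """
    if adjustment not in ("tukey", "none"):
        raise UsageError(f"unknown adjustment {adjustment!r}")
    if factor not in fit.design.levels:
        raise UsageError(f"factor {factor!r} not in fixed effects")
    levels = fit.design.levels[factor]
    if len(levels) < 2:
        return []
    mm = _marginal_mean_rows(fit.design, factor)
    k = len(levels)
    results = []
    for a, b in itertools.combinations(levels, 2):
        c = mm[a] - mm[b]
        est = float(c @ fit.params)
        se = float(np.sqrt(c @ fit.cov_params @ c))
        stat = est / se
        if fit.spec.family == GAUSSIAN_LOG10:
            df = satterthwaite_df(fit, c)
        else:
            df = _Z_DF
        p_un = float(2.0 * sps.t.sf(abs(stat), df))
        if adjustment == "tukey":
            p_adj = float(sps.studentized_range.sf(
                abs(stat) * np.sqrt(2.0), k, min(df, _Z_DF)))
        else:
            p_adj = p_un
        results.append(ContrastResult(
            pair=(a, b), estimate_link_scale=est, std_error=se,
            statistic=stat, df=float(df), p_unadjusted=p_un,
            p_adjusted=min(1.0, p_adj), adjustment=adjustment))
    return results


def contrasts_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "level_a": c.pair[0], "level_b": c.pair[1],
        "estimate_link_scale": c.estimate_link_scale,
        "std_error": c.std_error, "statistic": c.statistic, "df": c.df,
        "p_unadjusted": c.p_unadjusted, "p_adjusted": c.p_adjusted,
        "adjustment": c.adjustment} for c in contrasts])


def summarize(data: pd.DataFrame, grouping: list[str], value: str,
              experiment_col: str = "experiment_id",
              conf_level: float = 0.95) -> pd.DataFrame:
    """Cohort summary per group: N experiments, mean, SD, 95% CI half-widths.

    ``ci_wells`` uses the t quantile on well-level degrees of freedom;
    ``ci_experiments`` treats per-experiment means as the replicates.
    Groups with a single observation report SD 0 with ``sd_undefined``.
    """
    rows = []
    q = 1.0 - (1.0 - conf_level) / 2.0
    sub = data.dropna(subset=[value])
    for keys, g in sub.groupby(grouping, sort=True, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vals = g[value].to_numpy(dtype=float)
        n = len(vals)
        mean = float(np.mean(vals))
        sd_undefined = n < 2
        sd = 0.0 if sd_undefined else float(np.std(vals, ddof=1))
        ci_wells = (0.0 if sd_undefined
                    else float(sps.t.ppf(q, n - 1) * sd / np.sqrt(n)))
        exp_means = g.groupby(experiment_col, observed=True)[value].mean()
        n_exp = len(exp_means)
        if n_exp >= 2:
            ci_exp = float(sps.t.ppf(q, n_exp - 1)
                           * np.std(exp_means, ddof=1) / np.sqrt(n_exp))
        else:
            ci_exp = 0.0
        rows.append(dict(zip(grouping, keys)) | {
            "n_experiments": n_exp, "n_wells": n, "mean": mean, "sd": sd,
            "ci_wells": ci_wells, "ci_experiments": ci_exp,
            "sd_undefined": sd_undefined})
    return pd.DataFrame(rows)
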