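"""Shared model-specification and fit containers for mixed models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import UsageError, ValidationError
from .design import Design

GAUSSIAN_LOG10 = "gaussian_log10"
GAMMA_INVERSE = "gamma_inverse"


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, fixed factor terms, grouping factor, family.

    ``fixed`` lists factor names and optional two-way interactions
    (``"condition:treatment"``); ``random`` names the grouping column whose
    levels receive random intercepts (the independent experiments).
    """

    response: str
    fixed: tuple[str, ...] = ("condition",)
    random: str = "experiment_id"
    family: str = GAUSSIAN_LOG10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.family not in (GAUSSIAN_LOG10, GAMMA_INVERSE):
            raise UsageError(f"unknown family {self.family!r}")
        object.__setattr__(self, "fixed", tuple(self.fixed))

    def with_fixed(self, fixed: tuple[str, ...]) -> "ModelSpec":
        return ModelSpec(self.response, tuple(fixed), self.random,
                         self.family, self.alpha)

    def with_family(self, family: str) -> "ModelSpec":
        return ModelSpec(self.response, self.fixed, self.random,
                         family, self.alpha)


@dataclass
class MixedModelFit:
    """A fitted random-intercept mixed model (ML).

    ``coefficients`` maps design column names to (estimate, SE) on the
    model's link/transform scale: log10 units for the Gaussian family,
    inverse-mean units for the gamma family. ``residual_dispersion`` is
    the residual variance (Gaussian) or the reciprocal gamma shape
    (squared coefficient of variation).
    """

    spec: ModelSpec
    design: Design
    params: np.ndarray
    cov_params: np.ndarray
    random_intercept_variance: float
    residual_dispersion: float
    log_likelihood: float
    n_obs: int
    n_groups: int
    converged: bool
    method: str
    group_labels: list[str] = field(default_factory=list, repr=False)
    group_effects: np.ndarray | None = field(default=None, repr=False)
    _X: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)
    _group_idx: np.ndarray | None = field(default=None, repr=False)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.random_intercept_variance < 0:
            raise ValidationError("random-intercept variance must be >= 0")
        if self.n_obs < self.n_groups:
            raise ValidationError("n_obs must be >= n_groups")
        if self.converged and not np.isfinite(self.log_likelihood):
            raise ValidationError("converged fit must have finite log-likelihood")

    @property
    def coefficients(self) -> dict[str, tuple[float, float]]:
        se = np.sqrt(np.clip(np.diag(self.cov_params), 0, None))
        return {name: (float(b), float(s))
                for name, b, s in zip(self.design.column_names, self.params, se)}

    def pearson_residuals(self) -> np.ndarray:
        """Conditional (BLUP-adjusted) Pearson residuals."""
        eta = self._X @ self.params + self.group_effects[self._group_idx]
        if self.spec.family == GAUSSIAN_LOG10:
            return (self._y - eta) / np.sqrt(self.residual_dispersion)
        mu = 1.0 / eta
        # gamma variance is mu^2 * dispersion
        return (self._y - mu) / (mu * np.sqrt(self.residual_dispersion))

    def quantile_residuals(self) -> np.ndarray:
        """Conditional quantile (Dunn-Smyth) residuals.

        Standard normal under a correctly specified model for either
        family, hence comparable across families; for the Gaussian family
        they coincide with the standardized residuals.
        """
        from scipy import stats as sps
        eta = self._X @ self.params + self.group_effects[self._group_idx]
        if self.spec.family == GAUSSIAN_LOG10:
            return (self._y - eta) / np.sqrt(self.residual_dispersion)
        k = 1.0 / self.residual_dispersion
        mu = 1.0 / eta
        cdf = np.clip(sps.gamma.cdf(self._y, a=k, scale=mu / k),
                      1e-12, 1.0 - 1e-12)
        return sps.norm.ppf(cdf)


def prepare(data: pd.DataFrame, spec: ModelSpec
            ) -> tuple[np.ndarray, np.ndarray, Design, np.ndarray, list[str]]:
    """Validate data and build (y, X, design, group index, group labels)."""
    for col in (spec.response, spec.random):
        if col not in data.columns:
            raise UsageError(f"column {col!r} not in data")
    y = pd.to_numeric(data[spec.response], errors="raise").to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValidationError("non-finite response values")
    if np.any(y <= 0):
        raise ValidationError(
            "responses must be strictly positive for log10/gamma families; "
            "apply the exclusion rules for non-positive corrected baselines "
            "before modelling")
    design = Design.from_frame(data, spec.fixed)
    X = design.matrix(data)
    labels = sorted(data[spec.random].astype(str).unique())
    lookup = {g: i for i, g in enumerate(labels)}
    gidx = data[spec.random].astype(str).map(lookup).to_numpy(dtype=int)
    if len(labels) < 2:
        raise ValidationError(
            f"random factor {spec.random!r} needs >=2 levels, got {len(labels)}")
    return y, X, design, gidx, labels
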