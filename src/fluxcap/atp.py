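"""ATP quantification from luciferase luminescence readings.

Each 96-well luminometer plate carries its own standard curve: wells with
known amounts of ATP (amol per well) against measured relative light units
(RLU). Sample lysates are read in triplicate; the mean RLU is inverted
through the plate's curve and divided by the number of sperm represented
in the assayed lysate aliquot, giving amol ATP per sperm.

The default curve is a least-squares line RLU = slope * ATP + intercept
(5-s integration luciferase signals are near-linear over the assayed
range); a log-log power-law fit is available for plates with visible
curvature. Curves with r-squared below a threshold (default 0.98) are
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UsageError, ValidationError

STANDARDS_COLUMNS = ["plate_id", "known_atp_amol", "rlu"]
SAMPLES_COLUMNS = ["plate_id", "sample_id", "condition",
                   "rlu_1", "rlu_2", "rlu_3", "cells_in_aliquot"]


@dataclass(frozen=True)
class AtpStandardPoint:
    known_atp: float   # amol per well
    luminescence: float  # RLU

    def __post_init__(self) -> None:
        if self.known_atp < 0 or self.luminescence < 0:
            raise ValidationError("standard points must be non-negative")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted luminescence-vs-ATP calibration for one plate."""

    slope: float
    intercept: float
    r_squared: float
    form: str                 # "linear" | "loglog"
    atp_range: tuple[float, float]

    def atp_from_rlu(self, rlu: float) -> float:
        if self.form == "linear":
            return (rlu - self.intercept) / self.slope
        return float(np.exp((np.log(rlu) - self.intercept) / self.slope))

    def in_range(self, atp: float) -> bool:
        lo, hi = self.atp_range
        return lo <= atp <= hi


@dataclass(frozen=True)
class AtpResult:
    sample_id: str
    atp_amol_per_sperm: float
    mean_rlu: float
    extrapolated: bool
    clamped: bool


def fit_standard_curve(points: list[AtpStandardPoint], form: str = "linear",
                       min_r_squared: float = 0.98) -> StandardCurve:
    """Least-squares standard curve with an r-squared acceptance gate.

    Requires at least 3 points whose ATP amounts span at least one order
    of magnitude (zero-ATP blanks are allowed and excluded from the span
    check for the log-log form).
    """
    if form not in ("linear", "loglog"):
        raise UsageError(f"unknown curve form {form!r}")
    if len(points) < 3:
        raise ValidationError(f"need >=3 standard points, got {len(points)}")
    x = np.array([p.known_atp for p in points], dtype=float)
    y = np.array([p.luminescence for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("standard points have zero ATP variance")
    positive = x > 0
    if positive.sum() >= 2 and x[positive].max() / x[positive].min() < 10:
        raise ValidationError(
            "standard points must span at least one order of magnitude of ATP")
    if form == "loglog":
        if np.any(~positive) or np.any(y <= 0):
            x, y = x[positive & (y > 0)], y[positive & (y > 0)]
            if len(x) < 3:
                raise ValidationError("too few positive points for log-log fit")
        x, y = np.log(x), np.log(y)
    res = sps.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    if r2 < min_r_squared:
        raise ValidationError(
            f"standard curve rejected: r^2 = {r2:.4f} < {min_r_squared} "
            f"(slope {res.slope:.4g}, intercept {res.intercept:.4g})")
    atp_vals = np.array([p.known_atp for p in points])
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=r2, form=form,
                         atp_range=(float(atp_vals.min()), float(atp_vals.max())))


def atp_per_sperm(replicate_rlu: list[float] | np.ndarray,
                  cells_represented: float, curve: StandardCurve,
                  sample_id: str = "") -> AtpResult:
    """ATP content per sperm from replicate luminescence readings.

    The replicate mean is inverted through the curve; readings below the
    curve's blank are clamped to zero ATP and flagged, readings outside
    the standard range are flagged as extrapolated but kept.
    """
    rlu = np.asarray(replicate_rlu, dtype=float)
    if rlu.size < 1:
        raise ValidationError("need at least one replicate reading")
    if cells_represented <= 0:
        raise ValidationError("cells_represented must be positive")
    mean_rlu = float(np.mean(rlu))
    atp_total = curve.atp_from_rlu(mean_rlu)
    clamped = atp_total < 0
    if clamped:
        atp_total = 0.0
    extrapolated = not curve.in_range(atp_total) and not clamped
    return AtpResult(sample_id=sample_id,
                     atp_amol_per_sperm=atp_total / cells_represented,
                     mean_rlu=mean_rlu, extrapolated=extrapolated,
                     clamped=clamped)


def analyze_atp_tables(standards: pd.DataFrame, samples: pd.DataFrame,
                       form: str = "linear",
                       min_r_squared: float = 0.98) -> pd.DataFrame:
    """Per-plate curves + per-sample quantification from the CSV dialects.

    ``standards``: plate_id, known_atp_amol, rlu.
    ``samples``: plate_id, sample_id, condition, rlu_1..rlu_3,
    cells_in_aliquot. Returns one row per sample with the ATP content and
    curve/flag diagnostics.
    """
    for cols, df, name in ((STANDARDS_COLUMNS, standards, "standards"),
                           (SAMPLES_COLUMNS, samples, "samples")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"{name} table missing columns {missing}")
    curves = {}
    for plate_id, g in standards.groupby("plate_id"):
        pts = [AtpStandardPoint(r.known_atp_amol, r.rlu)
               for r in g.itertuples(index=False)]
        curves[plate_id] = fit_standard_curve(pts, form=form,
                                              min_r_squared=min_r_squared)
    rows = []
    for r in samples.itertuples(index=False):
        if r.plate_id not in curves:
            raise ValidationError(f"sample {r.sample_id}: no standards for "
                                  f"plate {r.plate_id}")
        curve = curves[r.plate_id]
        result = atp_per_sperm([r.rlu_1, r.rlu_2, r.rlu_3],
                               r.cells_in_aliquot, curve, str(r.sample_id))
        rows.append({
            "plate_id": r.plate_id, "sample_id": r.sample_id,
            "condition": r.condition,
            "atp_amol_per_sperm": result.atp_amol_per_sperm,
            "mean_rlu": result.mean_rlu, "curve_r_squared": curve.r_squared,
            "extrapolated": result.extrapolated, "clamped": result.clamped})
    return pd.DataFrame(rows)
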