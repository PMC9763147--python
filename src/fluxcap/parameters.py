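"""Bioenergetic parameter panel and modulator-response calculations.

All quantities are window arithmetic on normalized per-sperm traces.  With
the standard cycle plan (baseline 2-4, modulator 5-7, A+R 8-9):

* basal respiration       = mean OCR(baseline) - mean OCR(A+R)
* non-mito respiration    = mean OCR(A+R)
* proton leak %           = 100 * (mean OCR(5-7, oligomycin well) - OCR(A+R)) / basal
* respiratory ATP prod. % = 100 - proton leak %
* maximal respiration %   = 100 * (max OCR(5-7, FCCP well) - OCR(A+R)) / basal
* spare capacity %        = maximal % - 100
* basal glycolysis        = mean ECAR(baseline)          (no A+R correction)
* glycolytic reserve %    = 100 * (max ECAR(5-7, oligomycin well) - basal gly) / basal gly
* OCR/ECAR ratio          = mean OCR(baseline) / mean ECAR(baseline), per well

The FCCP-OCR and oligomycin-ECAR aggregates use the highest value among
the modulator cycles rather than the mean (transient peak responses);
everything else uses window means.

Modulator responses are expressed as percent of the well's own baseline.
For OCR, both the baseline and the modulator aggregate are first corrected
by subtracting the well's A+R mean, so that only mitochondrial respiration
enters the ratio; ECAR responses are uncorrected.  Two aggregation
conventions are provided: ``"mean"`` (mean of cycles 5-7 for both signals,
as in within-species condition/treatment tables) and ``"extremum"``
(ECAR uses max under oligomycin and min under 2DOG, as in the
between-species comparison).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import UndefinedPanelError, UsageError, ValidationError
from .plate import (AR_LEVEL, Condition, CycleWindows, NormalizedTrace,
                    Treatment, WellAnnotation)

log = logging.getLogger(__name__)

PANEL_QUANTITIES = [
    "basal_respiration", "nonmito_respiration", "proton_leak_pct",
    "atp_linked_pct", "maximal_respiration_pct", "spare_capacity_pct",
    "basal_glycolysis", "glycolytic_reserve_pct", "ocr_ecar_ratio",
]


@dataclass(frozen=True)
class WindowAggregate:
    """Mean/max/min of both signals over one analysis window of a well."""

    well_id: str
    window: str
    mode: str
    ocr_value: float
    ecar_value: float


class BasalRespiration(NamedTuple):
    """Basal respiration plus whether the A+R correction could be applied."""

    value: float
    nonmito: float
    ar_corrected: bool


def window_aggregate(trace: NormalizedTrace, windows: CycleWindows,
                     window: str, mode: str = "mean") -> WindowAggregate:
    """Aggregate both signals of a trace over one cycle window.

    ``mode`` is one of mean/max/min. Cycles in ``windows.discarded`` can
    never be requested because the window sets are disjoint by construction.
    """
    cycles = windows.window(window)
    if mode not in ("mean", "max", "min"):
        raise UsageError(f"unknown aggregation mode {mode!r}")
    fn = {"mean": np.mean, "max": np.max, "min": np.min}[mode]
    return WindowAggregate(
        well_id=trace.well_id, window=window, mode=mode,
        ocr_value=float(fn(trace.values_at(cycles, "OCR"))),
        ecar_value=float(fn(trace.values_at(cycles, "ECAR"))))


def _agg(trace: NormalizedTrace, windows: CycleWindows, window: str,
         signal: str, mode: str = "mean") -> float:
    fn = {"mean": np.mean, "max": np.max, "min": np.min}[mode]
    return float(fn(trace.values_at(windows.window(window), signal)))


def basal_respiration(trace: NormalizedTrace, windows: CycleWindows
                      ) -> BasalRespiration:
    """Baseline-window OCR minus the well's non-mitochondrial (A+R) floor.

    If the A+R cycles are absent (truncated run) the uncorrected baseline
    mean is returned with ``ar_corrected=False`` rather than failing the
    whole plate.
    """
    base = _agg(trace, windows, "baseline", "OCR")
    if trace.has_cycles(windows.ar):
        nonmito = _agg(trace, windows, "ar", "OCR")
        return BasalRespiration(base - nonmito, nonmito, True)
    return BasalRespiration(base, float("nan"), False)


def proton_leak_and_atp_linked(baseline_trace: NormalizedTrace,
                               oligo_trace: NormalizedTrace,
                               windows: CycleWindows) -> tuple[float, float]:
    """Proton leak and ATP-linked respiration as % of basal respiration.

    Leak is the oligomycin-insensitive, A+R-sensitive respiration of the
    oligomycin well, relative to the paired baseline well's basal
    respiration; ATP-linked respiration is its complement to 100%.
    """
    basal = basal_respiration(baseline_trace, windows).value
    if basal <= 0:
        raise UndefinedPanelError(
            f"well {baseline_trace.well_id}: basal respiration {basal:.4g} <= 0")
    leak_abs = (_agg(oligo_trace, windows, "treatment", "OCR")
                - _agg(oligo_trace, windows, "ar", "OCR"))
    leak = 100.0 * leak_abs / basal
    return leak, 100.0 - leak


def maximal_and_spare(fccp_trace: NormalizedTrace, windows: CycleWindows,
                      basal: float) -> tuple[float, float]:
    """Maximal (FCCP-uncoupled) respiration and spare capacity as % of basal.

    The FCCP response is transient, so the highest OCR among the modulator
    cycles is used instead of the window mean.
    """
    if basal <= 0:
        raise UndefinedPanelError(f"basal respiration {basal:.4g} <= 0")
    maximal_abs = (_agg(fccp_trace, windows, "treatment", "OCR", "max")
                   - _agg(fccp_trace, windows, "ar", "OCR"))
    maximal = 100.0 * maximal_abs / basal
    return maximal, maximal - 100.0


def glycolysis_panel(baseline_trace: NormalizedTrace,
                     oligo_trace: NormalizedTrace,
                     windows: CycleWindows) -> tuple[float, float]:
    """Basal glycolysis and glycolytic reserve (% of basal glycolysis).

    Basal glycolysis is the uncorrected baseline ECAR mean; the reserve is
    the rise of the oligomycin well's peak ECAR above it, in percent.
    """
    basal_gly = _agg(baseline_trace, windows, "baseline", "ECAR")
    if basal_gly <= 0:
        raise UndefinedPanelError(
            f"well {baseline_trace.well_id}: basal glycolysis {basal_gly:.4g} <= 0")
    peak = _agg(oligo_trace, windows, "treatment", "ECAR", "max")
    return basal_gly, 100.0 * (peak - basal_gly) / basal_gly


def ocr_ecar_ratio(trace: NormalizedTrace, windows: CycleWindows) -> float:
    """Basal-state OCR/ECAR ratio of one well (uncorrected rates).

    Cohort summaries must average per-well ratios, never divide cohort
    means.
    """
    ecar = _agg(trace, windows, "baseline", "ECAR")
    if ecar == 0:
        raise UndefinedPanelError(f"well {trace.well_id}: zero baseline ECAR")
    return _agg(trace, windows, "baseline", "OCR") / ecar


@dataclass(frozen=True)
class ResponseValue:
    """Modulator response of one well, as percent of its own baseline."""

    well_id: str
    signal: str          # "OCR" | "ECAR"
    treatment: str       # layout treatment token, or "ar"
    percent_of_baseline: float
    delta_percent: float
    aggregation: str     # "mean_5_7" | "max_5_7" | "min_5_7" | "mean_8_9"
    ar_corrected: bool


def _response_mode(signal: str, treatment: str, convention: str) -> str:
    if convention == "mean":
        return "mean"
    if convention == "extremum":
        if signal == "ECAR" and treatment == Treatment.OLIGOMYCIN.value:
            return "max"
        if signal == "ECAR" and treatment == Treatment.DOG2.value:
            return "min"
        return "mean"
    raise UsageError(f"unknown response convention {convention!r}")


def response_percent(trace: NormalizedTrace, windows: CycleWindows,
                     signal: str, treatment: str,
                     convention: str = "mean") -> ResponseValue:
    """Percent-of-baseline response of one signal to one modulator.

    ``treatment`` is the well's modulator token, or ``"ar"`` to quantify the
    response over the A+R window itself (meaningful for ECAR only, since
    OCR is A+R-corrected).  Raises :class:`UndefinedPanelError` when the
    (corrected) baseline is not positive; callers exclude such wells from
    downstream statistics.
    """
    if signal not in ("OCR", "ECAR"):
        raise UsageError(f"unknown signal {signal!r}")
    window = "ar" if treatment == AR_LEVEL else "treatment"
    mode = "mean" if treatment == AR_LEVEL else _response_mode(signal, treatment, convention)
    base = _agg(trace, windows, "baseline", signal)
    value = _agg(trace, windows, window, signal, mode)
    ar_corrected = signal == "OCR"
    if ar_corrected:
        floor = _agg(trace, windows, "ar", "OCR")
        base, value = base - floor, value - floor
    if base <= 0:
        raise UndefinedPanelError(
            f"well {trace.well_id}: corrected baseline {signal} {base:.4g} <= 0")
    pct = 100.0 * value / base
    suffix = {"baseline": "2_4", "treatment": "5_7", "ar": "8_9"}[window]
    return ResponseValue(
        well_id=trace.well_id, signal=signal, treatment=treatment,
        percent_of_baseline=pct, delta_percent=pct - 100.0,
        aggregation=f"{mode}_{suffix}", ar_corrected=ar_corrected)


def condition_percent_change(nc_mean: float, cap_mean: float,
                             direction: str) -> float:
    """Percent change of a cohort mean between incubation conditions.

    ``direction="decrease"`` reports 100*(nc-cap)/nc, ``"increase"``
    reports 100*(cap-nc)/nc; full precision is returned, display rounding
    is the caller's choice.
    """
    if nc_mean <= 0:
        raise UndefinedPanelError(f"non-positive reference mean {nc_mean:.4g}")
    if direction == "decrease":
        return 100.0 * (nc_mean - cap_mean) / nc_mean
    if direction == "increase":
        return 100.0 * (cap_mean - nc_mean) / nc_mean
    raise UsageError(f"unknown direction {direction!r}")


def _wells_by_treatment(annotations: Mapping[str, WellAnnotation],
                        experiment: str, condition: Condition,
                        treatment: Treatment) -> list[str]:
    return sorted(
        w for w, a in annotations.items()
        if not a.is_background and a.experiment_id == experiment
        and a.condition == condition and a.treatment == treatment)


def build_panel(traces: Mapping[str, NormalizedTrace],
                annotations: Mapping[str, WellAnnotation],
                windows: CycleWindows, pairing: str = "all") -> pd.DataFrame:
    """Assemble the per-well bioenergetic panel for a whole run.

    One row per baseline well.  Quantities that need an oligomycin or FCCP
    partner pair the baseline well with every candidate well of the same
    experiment and condition and average the pair results
    (``pairing="all"``), or use the first candidate (``pairing="first"``).
    Quantities undefined for a well (non-positive basal rates, no partner
    well) are NaN and the well is listed in the log.
    """
    if pairing not in ("all", "first"):
        raise UsageError(f"unknown pairing {pairing!r}")
    rows = []
    experiments = sorted({a.experiment_id for a in annotations.values()
                          if not a.is_background})
    for exp in experiments:
        for cond in Condition:
            base_wells = _wells_by_treatment(annotations, exp, cond, Treatment.BASELINE)
            oligo_wells = _wells_by_treatment(annotations, exp, cond, Treatment.OLIGOMYCIN)
            fccp_wells = _wells_by_treatment(annotations, exp, cond, Treatment.FCCP)
            if pairing == "first":
                oligo_wells, fccp_wells = oligo_wells[:1], fccp_wells[:1]
            for b in base_wells:
                tr = traces[b]
                basal = basal_respiration(tr, windows)
                row: dict[str, object] = {
                    "well_id": b, "experiment_id": exp, "condition": cond.value,
                    "basal_respiration": basal.value,
                    "nonmito_respiration": basal.nonmito,
                    "nonmito_uncorrected": not basal.ar_corrected,
                }
                for key in PANEL_QUANTITIES:
                    row.setdefault(key, np.nan)
                try:
                    row["ocr_ecar_ratio"] = ocr_ecar_ratio(tr, windows)
                except UndefinedPanelError as exc:
                    log.warning("panel: %s", exc)
                leaks, atps, reserves, gly = [], [], [], []
                for o in oligo_wells:
                    try:
                        lk, al = proton_leak_and_atp_linked(tr, traces[o], windows)
                        leaks.append(lk)
                        atps.append(al)
                    except UndefinedPanelError as exc:
                        log.warning("panel: %s", exc)
                    try:
                        g, r = glycolysis_panel(tr, traces[o], windows)
                        gly.append(g)
                        reserves.append(r)
                    except UndefinedPanelError as exc:
                        log.warning("panel: %s", exc)
                maxes, spares = [], []
                for f in fccp_wells:
                    try:
                        mx, sp = maximal_and_spare(traces[f], windows, basal.value)
                        maxes.append(mx)
                        spares.append(sp)
                    except UndefinedPanelError as exc:
                        log.warning("panel: %s", exc)
                if leaks:
                    row["proton_leak_pct"] = float(np.mean(leaks))
                    row["atp_linked_pct"] = float(np.mean(atps))
                if maxes:
                    row["maximal_respiration_pct"] = float(np.mean(maxes))
                    row["spare_capacity_pct"] = float(np.mean(spares))
                if gly:
                    row["basal_glycolysis"] = float(np.mean(gly))
                    row["glycolytic_reserve_pct"] = float(np.mean(reserves))
                else:
                    # basal glycolysis itself needs no partner well
                    try:
                        row["basal_glycolysis"] = _agg(tr, windows, "baseline", "ECAR")
                    except ValidationError:
                        pass
                rows.append(row)
    cols = (["well_id", "experiment_id", "condition"] + PANEL_QUANTITIES
            + ["nonmito_uncorrected"])
    return pd.DataFrame(rows, columns=cols)


def panel_long(panel: pd.DataFrame) -> pd.DataFrame:
    """Long format: one row per well per quantity (for tidy CSV output)."""
    return panel.melt(
        id_vars=["well_id", "experiment_id", "condition"],
        value_vars=PANEL_QUANTITIES,
        var_name="quantity", value_name="value").dropna(subset=["value"])


def build_responses(traces: Mapping[str, NormalizedTrace],
                    annotations: Mapping[str, WellAnnotation],
                    windows: CycleWindows,
                    convention: str = "mean") -> pd.DataFrame:
    """Percent-of-baseline responses for every measurement well.

    Each modulator-treated well yields one OCR and one ECAR response; the
    A+R response of ECAR is additionally computed for baseline wells
    (every well receives A+R, but only baseline wells isolate its effect).
    Wells with non-positive corrected baselines are excluded and counted in
    the log.
    """
    rows, excluded = [], 0
    for well_id in sorted(traces):
        ann = annotations[well_id]
        if ann.is_background:
            continue
        targets: list[tuple[str, str]] = []
        if ann.treatment == Treatment.BASELINE:
            targets.append(("ECAR", AR_LEVEL))
            targets.append(("OCR", Treatment.BASELINE.value))
            targets.append(("ECAR", Treatment.BASELINE.value))
        else:
            targets.append(("OCR", ann.treatment.value))
            targets.append(("ECAR", ann.treatment.value))
        for signal, level in targets:
            try:
                rv = response_percent(traces[well_id], windows, signal, level,
                                      convention)
            except UndefinedPanelError as exc:
                excluded += 1
                log.warning("responses: excluded %s", exc)
                continue
            rows.append({
                "well_id": well_id, "experiment_id": ann.experiment_id,
                "condition": ann.condition.value, "signal": signal,
                "treatment": level,
                "percent_of_baseline": rv.percent_of_baseline,
                "delta_percent": rv.delta_percent,
                "aggregation": rv.aggregation,
                "ar_corrected": rv.ar_corrected,
            })
    if excluded:
        log.warning("responses: %d well/signal values excluded "
                    "(non-positive corrected baseline)", excluded)
    return pd.DataFrame(rows, columns=[
        "well_id", "experiment_id", "condition", "signal", "treatment",
        "percent_of_baseline", "delta_percent", "aggregation", "ar_corrected"])
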