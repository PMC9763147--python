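"""Synthetic plate-assay data with the hierarchy the analysis assumes.

The generator emulates a 24-well extracellular flux experiment on sperm:
9 measurement cycles of 6 min; modulator injection after cycle 4 with a
first-order approach to the post-injection plateau; antimycin A + rotenone
(A+R) after cycle 7 collapsing OCR to a non-mitochondrial floor within one
cycle; cell-free background wells; per-experiment and per-well
multiplicative lognormal effects; per-cycle multiplicative measurement
noise; and per-well sperm counts, so that raw (pre-normalization) values
exercise the full pipeline end to end.

Calibration. Defaults are anchored to reported cohort values for
steppe-mouse (*Mus spicilegus*) sperm. Because the pipeline's window
arithmetic sees the onset transient and the A+R correction, plateau
multipliers are not set to the printed response percentages directly;
they are obtained by inverting the (noise-free) window arithmetic so that
the *derived* quantities land on the printed values: basal respiration
315 (NC) vs 231 (CAP) amol O2 min^-1 sperm^-1, basal glycolysis 18.9 vs
25.7 nano-pH min^-1 sperm^-1, OCR responses of 37.3% (oligomycin), 841%
(FCCP), 153% (2DOG) and 42.7% (oxamate) of baseline, ECAR responses of
147%, 72.1%, 63.0% and a 141% A+R level. The inversion is closed-form
(see :func:`ocr_plateau_for_response`). The two species presets differ in
the sign of the OCR response to the glycolysis inhibitor 2DOG:
*M. spicilegus* sperm increase respiration when glycolysis is blocked
(two-way metabolic compensation) while *M. musculus* sperm decrease it.

All multiplicative noise terms are mean-one lognormal, so configured
rates are also expected cohort rates. Same config + seed => identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .plate import (Condition, CycleWindows, PlateRun, Treatment,
                    WellAnnotation, WellTrace)

_TREATMENTS = tuple(t.value for t in Treatment)

#: onset rate per cycle for modulator injections: 95% of plateau by the
#: second post-injection cycle (1 - exp(-2r) = 0.95)
DEFAULT_ONSET_RATE = 1.498
#: A+R acts faster: respiration is essentially at the floor by the first
#: post-A+R measurement
DEFAULT_AR_ONSET_RATE = 6.0
#: non-mitochondrial OCR as a fraction of the pre-injection rate
DEFAULT_AR_OCR_FLOOR = 0.05


def _mean_one_lognormal(rng: np.random.Generator, sigma: float,
                        size=None) -> np.ndarray | float:
    """Multiplicative noise with expectation exactly 1."""
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size))


def _onset_fraction(rate: float, steps: np.ndarray) -> np.ndarray:
    """Fraction of the way to the plateau after `steps` >= 1 cycles."""
    return np.where(steps >= 1, 1.0 - np.exp(-rate * np.maximum(steps, 1)), 0.0)


def _window_constants(n_treatment: int = 3, n_ar: int = 2,
                      onset_rate: float = DEFAULT_ONSET_RATE,
                      ar_rate: float = DEFAULT_AR_ONSET_RATE,
                      floor: float = DEFAULT_AR_OCR_FLOOR
                      ) -> tuple[float, float, float]:
    """(g, alpha, beta): window-mean coefficients of the onset model.

    Over the modulator window the mean multiplier is 1 + (m-1)*g; over the
    A+R window the mean OCR multiplier is alpha*m + beta (decay from the
    plateau m toward floor).
    """
    g = float(np.mean(_onset_fraction(onset_rate, np.arange(1, n_treatment + 1))))
    h = float(np.mean(_onset_fraction(ar_rate, np.arange(1, n_ar + 1))))
    return g, 1.0 - h, floor * h


def ocr_plateau_for_response(percent_of_baseline: float,
                             n_treatment: int = 3, n_ar: int = 2,
                             onset_rate: float = DEFAULT_ONSET_RATE,
                             ar_rate: float = DEFAULT_AR_ONSET_RATE,
                             floor: float = DEFAULT_AR_OCR_FLOOR) -> float:
    """Plateau multiplier whose noiseless A+R-corrected OCR response equals
    the given percent of baseline.

    Inverts p = (mean57(m) - armean(m)) / (1 - armean(m)) with
    mean57(m) = 1 + (m-1) g and armean(m) = alpha m + beta.
    """
    p = percent_of_baseline / 100.0
    g, alpha, beta = _window_constants(n_treatment, n_ar, onset_rate, ar_rate, floor)
    return (p * (1.0 - beta) - 1.0 + g + beta) / (g - alpha + p * alpha)


def ecar_plateau_for_response(percent_of_baseline: float,
                              n_treatment: int = 3,
                              onset_rate: float = DEFAULT_ONSET_RATE) -> float:
    """Plateau multiplier whose noiseless uncorrected ECAR window mean
    equals the given percent of baseline."""
    g, _, _ = _window_constants(n_treatment=n_treatment, onset_rate=onset_rate)
    return 1.0 + (percent_of_baseline / 100.0 - 1.0) / g


def _ar_ecar_plateau(percent_of_baseline: float, n_ar: int = 2,
                     ar_rate: float = DEFAULT_AR_ONSET_RATE) -> float:
    h = float(np.mean(_onset_fraction(ar_rate, np.arange(1, n_ar + 1))))
    return 1.0 + (percent_of_baseline / 100.0 - 1.0) / h


def _basal_ocr_mean(target_basal: float) -> float:
    """Pre-injection OCR whose derived (A+R-corrected) basal respiration
    equals the target."""
    _, alpha, beta = _window_constants()
    return target_basal / (1.0 - alpha - beta)


def _default_condition_means() -> dict[str, tuple[float, float]]:
    return {"NC": (_basal_ocr_mean(315.0), 18.9),
            "CAP": (_basal_ocr_mean(231.0), 25.7)}


def _default_ocr_multipliers() -> dict[str, float]:
    return {"baseline": 1.0,
            "oligo": ocr_plateau_for_response(37.3),
            "fccp": ocr_plateau_for_response(841.0),
            "2dog": ocr_plateau_for_response(153.0),
            "oxamate": ocr_plateau_for_response(42.7)}


def _default_ecar_multipliers() -> dict[str, float]:
    return {"baseline": 1.0,
            "oligo": ecar_plateau_for_response(147.0),
            "fccp": 1.10,
            "2dog": ecar_plateau_for_response(72.1),
            "oxamate": ecar_plateau_for_response(63.0)}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic plate generator.

    Rates are per-sperm units (amol O2 min^-1 sperm^-1 for OCR, nano-pH
    min^-1 sperm^-1 for ECAR); multipliers are post-injection plateau
    factors on the pre-injection rate; noise SDs are natural-log scale.
    ``cycle_cv_ecar`` is much larger than ``cycle_cv_ocr``: the
    acidification signal rides on a small medium buffering change and its
    cycle-to-cycle scatter is what separates mean-window from peak-window
    response conventions.
    """

    n_experiments: int = 4
    wells_per_treatment: int = 2           # per condition per experiment
    treatments: tuple[str, ...] = _TREATMENTS
    # condition -> (pre-injection OCR, pre-injection ECAR)
    condition_means: dict[str, tuple[float, float]] = field(
        default_factory=_default_condition_means)
    ocr_multipliers: dict[str, float] = field(
        default_factory=_default_ocr_multipliers)
    ecar_multipliers: dict[str, float] = field(
        default_factory=_default_ecar_multipliers)
    ar_ocr_floor: float = DEFAULT_AR_OCR_FLOOR
    ar_ecar_mult: float = field(default_factory=lambda: _ar_ecar_plateau(141.0))
    between_experiment_sd: float = 0.35
    well_sd: float = 0.08
    cycle_cv_ocr: float = 0.06
    cycle_cv_ecar: float = 0.17
    bg_ocr_mean: float = 50.0              # pmol O2 min^-1 per well
    bg_ocr_sd: float = 2.0
    bg_ecar_mean: float = 5.0              # mpH min^-1 per well
    bg_ecar_sd: float = 0.3
    n_background: int = 4
    sperm_count_mean: float = 1.0e7
    sperm_count_sd_log: float = 0.10
    onset_rate: float = DEFAULT_ONSET_RATE
    ar_onset_rate: float = DEFAULT_AR_ONSET_RATE
    n_cycles: int = 9
    injection_cycle: int = 5
    ar_cycle: int = 8
    ocr_scale: float = 1e6                 # amol per pmol
    ecar_scale: float = 1e6                # nano-pH per mpH
    seed: int = 20221219

    def __post_init__(self) -> None:
        if self.n_experiments < 1 or self.wells_per_treatment < 1:
            raise ValidationError("need >=1 experiment and >=1 well per treatment")
        if self.n_background < 1:
            raise ValidationError("need >=1 background well per experiment")
        for cond, (ocr, ecar) in self.condition_means.items():
            if ocr <= 0 or ecar <= 0:
                raise ValidationError(f"condition {cond}: means must be > 0")
        for t in self.treatments:
            if t not in self.ocr_multipliers or t not in self.ecar_multipliers:
                raise ValidationError(f"treatment {t!r}: missing multipliers")
            if self.ocr_multipliers[t] <= 0 or self.ecar_multipliers[t] <= 0:
                raise ValidationError(f"treatment {t!r}: multipliers must be > 0")
        for name in ("between_experiment_sd", "well_sd", "cycle_cv_ocr",
                     "cycle_cv_ecar", "bg_ocr_sd", "bg_ecar_sd",
                     "sperm_count_sd_log"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 1 <= self.injection_cycle < self.ar_cycle <= self.n_cycles:
            raise ValidationError("need 1 <= injection_cycle < ar_cycle <= n_cycles")

    def windows(self) -> CycleWindows:
        return CycleWindows(
            discarded=frozenset({1}),
            baseline=frozenset(range(2, self.injection_cycle)),
            treatment=frozenset(range(self.injection_cycle, self.ar_cycle)),
            ar=frozenset(range(self.ar_cycle, self.n_cycles + 1)))


@dataclass
class GroundTruth:
    """Latent values realized by one generated run."""

    config: GeneratorConfig
    experiment_effects: dict[str, float]
    well_effects: dict[str, float]
    sperm_counts: dict[str, int]
    expected_per_sperm: pd.DataFrame   # well_id, cycle, ocr, ecar (noiseless)


def expected_multipliers(config: GeneratorConfig, treatment: str
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless per-cycle multiplier profiles (OCR, ECAR) for a treatment.

    Both signals start at 1, approach the treatment plateau from the
    injection cycle, then approach the A+R state (OCR: non-mito floor;
    ECAR: compensatory plateau) from the A+R cycle.
    """
    cycles = np.arange(1, config.n_cycles + 1)
    inj = _onset_fraction(config.onset_rate, cycles - config.injection_cycle + 1)
    ar = _onset_fraction(config.ar_onset_rate, cycles - config.ar_cycle + 1)
    ocr = 1.0 + (config.ocr_multipliers[treatment] - 1.0) * inj
    ecar = 1.0 + (config.ecar_multipliers[treatment] - 1.0) * inj
    ocr = ocr + (config.ar_ocr_floor - ocr) * ar
    ecar = ecar + (config.ar_ecar_mult - ecar) * ar
    return ocr, ecar


def expected_response_percent(config: GeneratorConfig, signal: str,
                              treatment: str, mode: str = "mean") -> float:
    """Noiseless percent-of-baseline response implied by the config.

    This is the plug-through of the pipeline's response formula on the
    expected multiplier profiles (A+R correction included for OCR), used
    as the generator's own oracle in recovery tests.
    """
    w = config.windows()
    m_ocr, m_ecar = expected_multipliers(
        config, treatment if treatment != "ar" else "baseline")
    m = m_ocr if signal == "OCR" else m_ecar
    idx = {c: i for i, c in enumerate(range(1, config.n_cycles + 1))}
    window = w.ar if treatment == "ar" else w.treatment
    fn = {"mean": np.mean, "max": np.max, "min": np.min}[mode]
    value = float(fn([m[idx[c]] for c in sorted(window)]))
    base = float(np.mean([m[idx[c]] for c in sorted(w.baseline)]))
    if signal == "OCR":
        floor = float(np.mean([m[idx[c]] for c in sorted(w.ar)]))
        base, value = base - floor, value - floor
    return 100.0 * value / base


def expected_basal(config: GeneratorConfig, condition: str,
                   signal: str = "OCR") -> float:
    """Noiseless derived basal rate (A+R-corrected for OCR) per condition."""
    w = config.windows()
    m_ocr, m_ecar = expected_multipliers(config, "baseline")
    idx = {c: i for i, c in enumerate(range(1, config.n_cycles + 1))}
    mean = config.condition_means[condition][0 if signal == "OCR" else 1]
    base = float(np.mean([(m_ocr if signal == "OCR" else m_ecar)[idx[c]]
                          for c in sorted(w.baseline)]))
    if signal == "OCR":
        base -= float(np.mean([m_ocr[idx[c]] for c in sorted(w.ar)]))
    return mean * base


def _well_names(n: int) -> list[str]:
    rows, cols = "ABCDEFGH", range(1, 13)
    names = [f"{r}{c}" for r in rows for c in cols]
    if n > len(names):
        names += [f"W{i}" for i in range(len(names), n)]
    return names[:n]


def generate_plate(config: GeneratorConfig,
                   seed: int | None = None) -> tuple[PlateRun, GroundTruth]:
    """Generate a raw (pre-normalization) multi-experiment run plus truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cycles = np.arange(1, config.n_cycles + 1)
    time_min = (cycles - 1) * 6.0
    traces: dict[str, WellTrace] = {}
    annotations: dict[str, WellAnnotation] = {}
    exp_effects: dict[str, float] = {}
    well_effects: dict[str, float] = {}
    sperm_counts: dict[str, int] = {}
    truth_rows = []

    mult_cache = {t: expected_multipliers(config, t) for t in config.treatments}

    for e in range(1, config.n_experiments + 1):
        exp_id = f"E{e}"
        exp_eff = float(_mean_one_lognormal(rng, config.between_experiment_sd))
        exp_effects[exp_id] = exp_eff
        n_meas = (len(config.condition_means) * len(config.treatments)
                  * config.wells_per_treatment)
        names = _well_names(n_meas + config.n_background)
        i = 0
        for cond_key in config.condition_means:
            cond = Condition(cond_key)
            ocr_mean, ecar_mean = config.condition_means[cond_key]
            for t in config.treatments:
                m_ocr, m_ecar = mult_cache[t]
                for _ in range(config.wells_per_treatment):
                    well_id = f"{exp_id}:{names[i]}"
                    i += 1
                    well_eff = float(_mean_one_lognormal(rng, config.well_sd))
                    count = int(round(config.sperm_count_mean
                                      * _mean_one_lognormal(
                                          rng, config.sperm_count_sd_log)))
                    exp_ocr = ocr_mean * exp_eff * well_eff * m_ocr
                    exp_ecar = ecar_mean * exp_eff * well_eff * m_ecar
                    obs_ocr = exp_ocr * _mean_one_lognormal(
                        rng, config.cycle_cv_ocr, config.n_cycles)
                    obs_ecar = exp_ecar * _mean_one_lognormal(
                        rng, config.cycle_cv_ecar, config.n_cycles)
                    raw_ocr = (obs_ocr * count / config.ocr_scale
                               + config.bg_ocr_mean)
                    raw_ecar = (obs_ecar * count / config.ecar_scale
                                + config.bg_ecar_mean)
                    if config.bg_ocr_sd:
                        raw_ocr = raw_ocr + rng.normal(
                            0, config.bg_ocr_sd, config.n_cycles)
                    if config.bg_ecar_sd:
                        raw_ecar = raw_ecar + rng.normal(
                            0, config.bg_ecar_sd, config.n_cycles)
                    traces[well_id] = WellTrace(
                        well_id=well_id, cycle_index=cycles,
                        time_min=time_min, ocr=raw_ocr, ecar=raw_ecar)
                    annotations[well_id] = WellAnnotation(
                        well_id=well_id, experiment_id=exp_id,
                        condition=cond, treatment=Treatment(t),
                        sperm_count=count)
                    well_effects[well_id] = well_eff
                    sperm_counts[well_id] = count
                    for ci, c in enumerate(cycles):
                        truth_rows.append((well_id, int(c),
                                           exp_ocr[ci], exp_ecar[ci]))
        for b in range(config.n_background):
            well_id = f"{exp_id}:{names[n_meas + b]}"
            bg_ocr = np.full(config.n_cycles, config.bg_ocr_mean)
            bg_ecar = np.full(config.n_cycles, config.bg_ecar_mean)
            if config.bg_ocr_sd:
                bg_ocr = bg_ocr + rng.normal(0, config.bg_ocr_sd, config.n_cycles)
            if config.bg_ecar_sd:
                bg_ecar = bg_ecar + rng.normal(0, config.bg_ecar_sd, config.n_cycles)
            traces[well_id] = WellTrace(
                well_id=well_id, cycle_index=cycles, time_min=time_min,
                ocr=bg_ocr, ecar=bg_ecar)
            annotations[well_id] = WellAnnotation(
                well_id=well_id, experiment_id=exp_id, is_background=True)

    run = PlateRun(run_id=f"sim-{config.seed if seed is None else seed}",
                   traces=traces, annotations=annotations,
                   windows=config.windows())
    truth = GroundTruth(
        config=config, experiment_effects=exp_effects,
        well_effects=well_effects, sperm_counts=sperm_counts,
        expected_per_sperm=pd.DataFrame(
            truth_rows, columns=["well_id", "cycle", "ocr", "ecar"]))
    return run, truth


def species_phenotype(name: str) -> GeneratorConfig:
    """Preset generator configs for the two murine metabolic phenotypes.

    ``"spicilegus"`` (steppe mouse): two-way metabolic compensation — OCR
    rises when glycolysis is blocked with 2DOG. ``"musculus"`` (house
    mouse): 2DOG inhibits both glycolysis and respiration (OCR falls to
    roughly oligomycin levels). Both show the compensatory ECAR rise under
    oligomycin. The musculus preset also encodes the stronger condition
    shift of that species (basal OCR -37%, basal ECAR +52% with
    capacitation); its absolute rates are on a different instrument scale
    and are nominal.
    """
    if name == "spicilegus":
        return GeneratorConfig()
    if name == "musculus":
        base = GeneratorConfig()
        return replace(
            base,
            condition_means={"NC": (_basal_ocr_mean(100.0), 20.0),
                             "CAP": (_basal_ocr_mean(63.0), 30.4)},
            ocr_multipliers={**base.ocr_multipliers,
                             "oligo": ocr_plateau_for_response(27.4),
                             "2dog": ocr_plateau_for_response(28.8)},
            ecar_multipliers={**base.ecar_multipliers,
                              "oligo": 1.611, "2dog": 0.393})
    raise ConfigurationError(
        f"unknown species preset {name!r} (expected spicilegus or musculus)")


def generate_null_dataset(config: GeneratorConfig, n_replicates: int
                          ) -> Iterator[pd.DataFrame]:
    """Stream of well-level null datasets for type-I-error studies.

    Requires identical condition means (otherwise the datasets are not
    null). Each replicate draws fresh experiment effects and well noise;
    replicate seeds derive deterministically from ``config.seed``. The
    per-well value emulates a baseline-window mean OCR: well effect times
    cycle noise averaged over the baseline cycles.
    """
    if len({m for m in config.condition_means.values()}) != 1:
        raise ConfigurationError(
            "null datasets require identical means in all conditions")
    wells = config.wells_per_treatment * len(config.treatments)
    n_base = max(len(config.windows().baseline), 1)
    sd_well = float(np.sqrt(config.well_sd ** 2
                            + config.cycle_cv_ocr ** 2 / n_base))
    children = np.random.SeedSequence(config.seed).spawn(n_replicates)
    for rep_seq in children:
        rng = np.random.default_rng(rep_seq)
        rows = []
        for e in range(1, config.n_experiments + 1):
            exp_eff = _mean_one_lognormal(rng, config.between_experiment_sd)
            for cond in config.condition_means:
                mean_ocr = config.condition_means[cond][0]
                vals = (mean_ocr * exp_eff
                        * _mean_one_lognormal(rng, sd_well, wells))
                for v in vals:
                    rows.append((f"E{e}", cond, float(v)))
        yield pd.DataFrame(rows, columns=["experiment_id", "condition", "value"])


@dataclass(frozen=True)
class AtpAssayConfig:
    """Synthetic luciferase-assay generator (standards + triplicate samples).

    True per-sperm ATP means follow the reported condition effect
    (capacitating incubation lowers sperm ATP); the standards span the
    sample range so quantification needs no extrapolation.
    """

    n_experiments: int = 3
    # condition -> true mean ATP, amol per sperm
    condition_means: dict[str, float] = field(
        default_factory=lambda: {"NC": 1242.0, "CAP": 701.0})
    between_sample_sd: float = 0.25        # log-scale SD across experiments
    replicate_cv: float = 0.03             # luminometer replicate noise
    cells_in_aliquot: float = 5e5
    slope: float = 1e-5                    # RLU per amol ATP
    intercept: float = 50.0                # blank RLU
    standards_amol: tuple[float, ...] = (1e7, 3e7, 1e8, 3e8, 1e9, 3e9)
    curve_cv: float = 0.01
    seed: int = 20221219


def generate_atp_tables(config: AtpAssayConfig, seed: int | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Standards table, samples table, and the per-sample ATP truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    std_rows = []
    for amol in config.standards_amol:
        rlu = ((config.intercept + config.slope * amol)
               * _mean_one_lognormal(rng, config.curve_cv))
        std_rows.append(("P1", amol, float(rlu)))
    standards = pd.DataFrame(std_rows, columns=["plate_id", "known_atp_amol", "rlu"])
    sample_rows, truth_rows = [], []
    for e in range(1, config.n_experiments + 1):
        for cond, mean in config.condition_means.items():
            true_atp = float(mean * _mean_one_lognormal(
                rng, config.between_sample_sd))
            total = true_atp * config.cells_in_aliquot
            base_rlu = config.intercept + config.slope * total
            reps = base_rlu * _mean_one_lognormal(rng, config.replicate_cv, 3)
            sample_rows.append(("P1", f"S{e}-{cond}", cond,
                                *(float(r) for r in reps),
                                config.cells_in_aliquot))
            truth_rows.append((f"S{e}-{cond}", cond, true_atp))
    samples = pd.DataFrame(sample_rows, columns=[
        "plate_id", "sample_id", "condition", "rlu_1", "rlu_2", "rlu_3",
        "cells_in_aliquot"])
    truth = pd.DataFrame(truth_rows,
                         columns=["sample_id", "condition", "true_atp"])
    return standards, samples, truth
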