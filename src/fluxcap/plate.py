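"""Core containers for plate-based extracellular flux runs.

A run is a set of wells on one or more 24-well plates. Each well carries a
kinetic trace: one (OCR, ECAR) pair per measurement cycle of the flux
analyzer. Wells are annotated with the experiment they belong to, the
incubation condition of the sperm suspension (non-capacitating vs
capacitating), the modulator injected after the baseline cycles, the number
of sperm in the well, and whether the well is a cell-free background well.

Cycle bookkeeping is explicit: the instrument records 9 cycles of 6 min,
the first cycle is unstable and excluded from all statistics, cycles 2-4
are the pre-injection baseline, the modulator acts over cycles 5-7, and
antimycin A + rotenone (A+R) silence mitochondrial respiration over cycles
8-9. :class:`CycleWindows` encodes exactly this partition and every
downstream aggregation refers to it, never to hard-coded indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import numpy as np

from .errors import ValidationError


class Condition(str, Enum):
    """Incubation condition of the sperm suspension prior to the assay."""

    NON_CAPACITATING = "NC"
    CAPACITATING = "CAP"


class Treatment(str, Enum):
    """Modulator injected after the baseline cycles.

    ``BASELINE`` wells receive plain assay medium; every well additionally
    receives A+R before the final cycles, so A+R is not a layout-level
    treatment but a window of every trace.
    """

    BASELINE = "baseline"
    OLIGOMYCIN = "oligo"
    FCCP = "fccp"
    DOG2 = "2dog"
    OXAMATE = "oxamate"


#: Response-table rows also carry an "after A+R" level that is not a
#: seeded treatment; it is the A+R window of baseline wells.
AR_LEVEL = "ar"


@dataclass(frozen=True)
class CycleWindows:
    """Partition of measurement cycles into analysis windows.

    Defaults follow the standard 9-cycle protocol: discard cycle 1,
    baseline = cycles 2-4, modulator = cycles 5-7, A+R = cycles 8-9.
    """

    discarded: frozenset[int] = frozenset({1})
    baseline: frozenset[int] = frozenset({2, 3, 4})
    treatment: frozenset[int] = frozenset({5, 6, 7})
    ar: frozenset[int] = frozenset({8, 9})

    def __post_init__(self) -> None:
        sets = [self.discarded, self.baseline, self.treatment, self.ar]
        for name, s in zip(("discarded", "baseline", "treatment", "ar"), sets):
            object.__setattr__(self, name, frozenset(int(c) for c in s))
        sets = [self.discarded, self.baseline, self.treatment, self.ar]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValidationError("cycle windows must be pairwise disjoint")
        if self.baseline and self.treatment and max(self.baseline) >= min(self.treatment):
            raise ValidationError("baseline window must precede treatment window")
        if self.treatment and self.ar and max(self.treatment) >= min(self.ar):
            raise ValidationError("treatment window must precede A+R window")

    def window(self, name: str) -> frozenset[int]:
        try:
            return {"baseline": self.baseline, "treatment": self.treatment,
                    "ar": self.ar}[name]
        except KeyError:
            raise ValidationError(f"unknown window {name!r}") from None


@dataclass(frozen=True)
class WellTrace:
    """One well's kinetic trace of raw instrument rates.

    OCR in pmol O2 min^-1 per well, ECAR in mpH min^-1 per well. Cycle
    indices are 1-based and strictly increasing; times are minutes from the
    start of the first measurement cycle and are carried for plotting only.
    """

    well_id: str
    cycle_index: np.ndarray  # int, 1-based
    time_min: np.ndarray
    ocr: np.ndarray
    ecar: np.ndarray

    def __post_init__(self) -> None:
        ci = np.asarray(self.cycle_index, dtype=int)
        object.__setattr__(self, "cycle_index", ci)
        for name in ("time_min", "ocr", "ecar"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(ci)
        if any(len(getattr(self, f)) != n for f in ("time_min", "ocr", "ecar")):
            raise ValidationError(f"well {self.well_id}: ragged trace columns")
        if n == 0:
            raise ValidationError(f"well {self.well_id}: empty trace")
        if np.any(np.diff(ci) <= 0):
            raise ValidationError(
                f"well {self.well_id}: cycle indices must be strictly increasing")
        if np.any(np.diff(self.time_min) < 0):
            raise ValidationError(f"well {self.well_id}: time must be non-decreasing")
        if not (np.all(np.isfinite(self.ocr)) and np.all(np.isfinite(self.ecar))):
            raise ValidationError(f"well {self.well_id}: non-finite rate values")

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_index)

    def signal(self, name: str) -> np.ndarray:
        if name == "OCR":
            return self.ocr
        if name == "ECAR":
            return self.ecar
        raise ValidationError(f"unknown signal {name!r}")

    def values_at(self, cycles: Iterable[int], signal: str) -> np.ndarray:
        """Signal values at the given cycle indices, in cycle order."""
        wanted = sorted(int(c) for c in cycles)
        pos = {int(c): i for i, c in enumerate(self.cycle_index)}
        missing = [c for c in wanted if c not in pos]
        if missing:
            raise ValidationError(
                f"well {self.well_id}: cycles {missing} absent from trace")
        return self.signal(signal)[[pos[c] for c in wanted]]


@dataclass(frozen=True)
class WellAnnotation:
    """Design annotation for a well.

    Background (cell-free) wells carry no condition, treatment or sperm
    count; every measurement well carries all three.
    """

    well_id: str
    experiment_id: str
    condition: Condition | None = None
    treatment: Treatment | None = None
    sperm_count: int | None = None
    is_background: bool = False

    def __post_init__(self) -> None:
        if not self.is_background:
            if self.condition is None or self.treatment is None:
                raise ValidationError(
                    f"well {self.well_id}: measurement wells need condition and treatment")
            if self.sperm_count is None or self.sperm_count <= 0:
                raise ValidationError(
                    f"well {self.well_id}: sperm_count must be a positive integer")


@dataclass(frozen=True)
class PlateRun:
    """A validated set of traces + annotations sharing one cycle plan."""

    run_id: str
    traces: dict[str, WellTrace]
    annotations: dict[str, WellAnnotation]
    windows: CycleWindows = field(default_factory=CycleWindows)

    def __post_init__(self) -> None:
        t, a = set(self.traces), set(self.annotations)
        if t != a:
            raise ValidationError(
                f"run {self.run_id}: traces/annotations mismatch "
                f"(traces only: {sorted(t - a)}, layout only: {sorted(a - t)})")
        counts = {tr.n_cycles for tr in self.traces.values()}
        if len(counts) > 1:
            raise ValidationError(
                f"run {self.run_id}: traces have differing cycle counts {sorted(counts)}")

    @property
    def well_ids(self) -> list[str]:
        return sorted(self.traces)

    @property
    def experiment_ids(self) -> list[str]:
        return sorted({a.experiment_id for a in self.annotations.values()})

    def background_wells(self, experiment_id: str | None = None) -> list[str]:
        return sorted(
            w for w, a in self.annotations.items()
            if a.is_background and (experiment_id is None or a.experiment_id == experiment_id))

    def measurement_wells(self) -> list[str]:
        return sorted(w for w, a in self.annotations.items() if not a.is_background)

    def with_traces(self, traces: dict[str, WellTrace],
                    annotations: dict[str, WellAnnotation] | None = None) -> "PlateRun":
        return replace(self, traces=traces,
                       annotations=annotations if annotations is not None else self.annotations)


@dataclass(frozen=True)
class NormalizedTrace:
    """Per-sperm, background-corrected rates for one well.

    OCR in amol O2 min^-1 sperm^-1, ECAR in nano-pH min^-1 sperm^-1.
    Values may be negative after background correction; clamping decisions
    belong to the statistics layer.
    """

    well_id: str
    cycle_index: np.ndarray
    ocr: np.ndarray
    ecar: np.ndarray

    def __post_init__(self) -> None:
        ci = np.asarray(self.cycle_index, dtype=int)
        object.__setattr__(self, "cycle_index", ci)
        for name in ("ocr", "ecar"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if len(v) != len(ci):
                raise ValidationError(f"well {self.well_id}: ragged normalized trace")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"well {self.well_id}: non-finite normalized values")

    def signal(self, name: str) -> np.ndarray:
        if name == "OCR":
            return self.ocr
        if name == "ECAR":
            return self.ecar
        raise ValidationError(f"unknown signal {name!r}")

    def values_at(self, cycles: Iterable[int], signal: str) -> np.ndarray:
        wanted = sorted(int(c) for c in cycles)
        pos = {int(c): i for i, c in enumerate(self.cycle_index)}
        missing = [c for c in wanted if c not in pos]
        if missing:
            raise ValidationError(
                f"well {self.well_id}: cycles {missing} absent from trace")
        return self.signal(signal)[[pos[c] for c in wanted]]

    def has_cycles(self, cycles: Iterable[int]) -> bool:
        return set(int(c) for c in cycles) <= set(int(c) for c in self.cycle_index)
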