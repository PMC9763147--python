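"""Background correction and per-sperm normalization of raw plate rates.

Cell-free wells on each plate track the instrument/medium background; the
per-cycle mean of those wells is subtracted from every measurement well of
the same experiment. Corrected rates are then divided by the number of
sperm in the well and rescaled to per-cell units:

* OCR: pmol O2 min^-1 well^-1  ->  amol O2 min^-1 sperm^-1 (x 1e6 / count)
* ECAR: mpH min^-1 well^-1     ->  nano-pH min^-1 sperm^-1 (x 1e6 / count)

Correction precedes normalization: the background is an instrument-level
signal per well, so subtracting it from per-sperm values would mix units.
Corrected values may be negative; they are retained here and handled by
the exclusion rules of the statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .plate import NormalizedTrace, PlateRun, WellTrace

#: amol per pmol and nano-pH per mpH.
DEFAULT_OCR_SCALE = 1e6
DEFAULT_ECAR_SCALE = 1e6


@dataclass(frozen=True)
class UnitScale:
    """Conversion constants from raw instrument units to per-sperm units."""

    ocr_scale: float = DEFAULT_OCR_SCALE
    ecar_scale: float = DEFAULT_ECAR_SCALE


def background_correct(run: PlateRun) -> PlateRun:
    """Subtract the per-cycle mean of each experiment's background wells.

    Returns a new run containing only measurement wells. Requires at least
    one background well per experiment (:class:`ConfigurationError`
    otherwise).
    """
    bg_mean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for exp in run.experiment_ids:
        bg_wells = run.background_wells(exp)
        if not bg_wells:
            raise ConfigurationError(f"experiment {exp}: no background wells")
        ocr = np.mean([run.traces[w].ocr for w in bg_wells], axis=0)
        ecar = np.mean([run.traces[w].ecar for w in bg_wells], axis=0)
        bg_mean[exp] = (ocr, ecar)

    traces: dict[str, WellTrace] = {}
    annotations = {}
    for well_id in run.measurement_wells():
        tr = run.traces[well_id]
        ocr_bg, ecar_bg = bg_mean[run.annotations[well_id].experiment_id]
        traces[well_id] = WellTrace(
            well_id=well_id, cycle_index=tr.cycle_index, time_min=tr.time_min,
            ocr=tr.ocr - ocr_bg, ecar=tr.ecar - ecar_bg)
        annotations[well_id] = run.annotations[well_id]
    return run.with_traces(traces, annotations)


def normalize_per_sperm(run: PlateRun, scale: UnitScale = UnitScale()
                        ) -> dict[str, NormalizedTrace]:
    """Convert a background-corrected run to per-sperm rates.

    Background wells, if still present, are rejected (they have no sperm
    count); call :func:`background_correct` first.
    """
    out: dict[str, NormalizedTrace] = {}
    for well_id in run.well_ids:
        ann = run.annotations[well_id]
        if ann.is_background:
            raise ValidationError(
                f"well {well_id}: background wells cannot be normalized; "
                "apply background_correct first")
        if ann.sperm_count is None or ann.sperm_count <= 0:
            raise ValidationError(f"well {well_id}: missing sperm_count")
        tr = run.traces[well_id]
        out[well_id] = NormalizedTrace(
            well_id=well_id, cycle_index=tr.cycle_index,
            ocr=tr.ocr * scale.ocr_scale / ann.sperm_count,
            ecar=tr.ecar * scale.ecar_scale / ann.sperm_count)
    return out
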