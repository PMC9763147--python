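"""Shared fixtures: tiny hand-built traces and small generated runs."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from fluxcap.plate import CycleWindows, NormalizedTrace, WellTrace
from fluxcap.simulate import GeneratorConfig, generate_plate

logging.getLogger("fluxcap").setLevel(logging.ERROR)


def make_normalized(well_id: str, ocr, ecar, n_cycles: int = 9) -> NormalizedTrace:
    """Build a 9-cycle normalized trace from per-cycle value lists."""
    ocr = np.asarray(ocr, dtype=float)
    ecar = np.asarray(ecar, dtype=float)
    assert len(ocr) == len(ecar) == n_cycles
    return NormalizedTrace(well_id=well_id,
                           cycle_index=np.arange(1, n_cycles + 1),
                           ocr=ocr, ecar=ecar)


def flat_trace(well_id: str, baseline: float, treat: float, ar: float,
               ecar_baseline: float = 20.0, ecar_treat: float = 20.0,
               ecar_ar: float = 20.0) -> NormalizedTrace:
    """Piecewise-constant trace: cycles 1-4 baseline, 5-7 treated, 8-9 A+R."""
    ocr = [baseline] * 4 + [treat] * 3 + [ar] * 2
    ecar = [ecar_baseline] * 4 + [ecar_treat] * 3 + [ecar_ar] * 2
    return make_normalized(well_id, ocr, ecar)


@pytest.fixture
def windows() -> CycleWindows:
    return CycleWindows()


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_experiments=2, wells_per_treatment=1, seed=1234)


@pytest.fixture(scope="session")
def small_run(small_config):
    return generate_plate(small_config)


def random_trace(rng: np.random.Generator, well_id: str = "W") -> NormalizedTrace:
    """A random 9-cycle trace (values may be negative, as after correction)."""
    return make_normalized(well_id,
                           rng.normal(100, 40, 9), rng.normal(30, 12, 9))
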