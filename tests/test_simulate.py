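"""Synthetic plate generator: determinism, limits, and recovery."""

from __future__ import annotations

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from fluxcap.errors import ConfigurationError
from fluxcap.io import traces_frame
from fluxcap.normalize import background_correct, normalize_per_sperm
from fluxcap.parameters import build_panel, build_responses
from fluxcap.simulate import (GeneratorConfig, expected_basal,
                              expected_response_percent, generate_null_dataset,
                              generate_plate, species_phenotype)


def noiseless(config: GeneratorConfig, **overrides) -> GeneratorConfig:
    return dataclasses.replace(
        config, between_experiment_sd=0.0, well_sd=0.0, cycle_cv_ocr=0.0,
        cycle_cv_ecar=0.0, bg_ocr_sd=0.0, bg_ecar_sd=0.0,
        sperm_count_sd_log=0.0, **overrides)


def test_same_seed_gives_identical_csv_bytes():
    cfg = GeneratorConfig(n_experiments=2, seed=5)
    buf1, buf2 = io.StringIO(), io.StringIO()
    traces_frame(generate_plate(cfg)[0]).to_csv(buf1, index=False)
    traces_frame(generate_plate(cfg)[0]).to_csv(buf2, index=False)
    assert buf1.getvalue() == buf2.getvalue()
    buf3 = io.StringIO()
    traces_frame(generate_plate(cfg, seed=6)[0]).to_csv(buf3, index=False)
    assert buf1.getvalue() != buf3.getvalue()


def test_noiseless_no_effect_wells_sit_at_condition_means():
    """Zero noise and unit multipliers: every normalized trace is constant
    at its condition mean after background correction."""
    cfg = noiseless(
        GeneratorConfig(n_experiments=1, wells_per_treatment=1),
        ocr_multipliers={t: 1.0 for t in GeneratorConfig().treatments},
        ecar_multipliers={t: 1.0 for t in GeneratorConfig().treatments},
        ar_ocr_floor=1.0, ar_ecar_mult=1.0)
    run, _ = generate_plate(cfg)
    normalized = normalize_per_sperm(background_correct(run))
    for well_id, tr in normalized.items():
        cond = run.annotations[well_id].condition.value
        ocr_mean, ecar_mean = cfg.condition_means[cond]
        np.testing.assert_allclose(tr.ocr, ocr_mean, rtol=1e-9)
        np.testing.assert_allclose(tr.ecar, ecar_mean, rtol=1e-9)


def test_noiseless_pipeline_reproduces_configured_responses():
    """Plug-through: the pipeline's response percentages on a noiseless
    plate equal the generator's own closed-form expectations."""
    cfg = noiseless(GeneratorConfig(n_experiments=1, wells_per_treatment=1))
    run, _ = generate_plate(cfg)
    normalized = normalize_per_sperm(background_correct(run))
    resp = build_responses(normalized, run.annotations, run.windows)
    for (signal, treatment), grp in resp.groupby(["signal", "treatment"]):
        expected = expected_response_percent(cfg, signal, treatment)
        np.testing.assert_allclose(grp.percent_of_baseline, expected,
                                   rtol=1e-9)
    panel = build_panel(normalized, run.annotations, run.windows)
    np.testing.assert_allclose(
        panel[panel.condition == "NC"].basal_respiration,
        expected_basal(cfg, "NC"), rtol=1e-9)


def test_moment_check_observations_average_to_expectation():
    """Mean of observation/expectation over many well-cycles -> 1."""
    cfg = dataclasses.replace(GeneratorConfig(n_experiments=6, seed=31),
                              bg_ocr_sd=0.0, bg_ecar_sd=0.0)
    run, truth = generate_plate(cfg)
    normalized = normalize_per_sperm(background_correct(run))
    ratios = []
    exp = truth.expected_per_sperm.set_index(["well_id", "cycle"])
    for well_id, tr in normalized.items():
        for i, c in enumerate(tr.cycle_index):
            ratios.append(tr.ocr[i] / exp.loc[(well_id, int(c)), "ocr"])
    ratios = np.asarray(ratios)
    tol = 4 * ratios.std() / np.sqrt(len(ratios))
    assert abs(ratios.mean() - 1.0) < max(tol, 1e-3)


def test_full_pipeline_recovers_configured_basal_means():
    """At 6 experiments the cohort basal respiration and glycolysis land
    within 2 SE (over experiment means) of the configured truth."""
    cfg = GeneratorConfig(n_experiments=6, seed=202)
    run, _ = generate_plate(cfg)
    normalized = normalize_per_sperm(background_correct(run))
    panel = build_panel(normalized, run.annotations, run.windows)
    for cond in ("NC", "CAP"):
        for col, target in (("basal_respiration", expected_basal(cfg, cond)),
                            ("basal_glycolysis",
                             cfg.condition_means[cond][1])):
            per_exp = (panel[panel.condition == cond]
                       .groupby("experiment_id")[col].mean())
            se = per_exp.std(ddof=1) / np.sqrt(len(per_exp))
            assert abs(per_exp.mean() - target) < 2 * se + 1e-9, (cond, col)


def test_null_stream_properties():
    cfg = GeneratorConfig(treatments=("baseline",), wells_per_treatment=5,
                          condition_means={"NC": (300.0, 20.0),
                                           "CAP": (300.0, 20.0)}, seed=8)
    reps = list(generate_null_dataset(cfg, 3))
    assert len(reps) == 3
    assert all(len(r) == 2 * 4 * 5 for r in reps)
    assert not reps[0].equals(reps[1])
    again = list(generate_null_dataset(cfg, 3))
    assert reps[0].equals(again[0])
    assert list(generate_null_dataset(cfg, 0)) == []
    with pytest.raises(ConfigurationError, match="identical"):
        next(iter(generate_null_dataset(GeneratorConfig(), 1)))


def test_species_presets_expected_signs():
    spic = species_phenotype("spicilegus")
    mus = species_phenotype("musculus")
    assert expected_response_percent(spic, "OCR", "2dog") > 100
    assert expected_response_percent(mus, "OCR", "2dog") < 100
    for cfg in (spic, mus):
        assert expected_response_percent(cfg, "ECAR", "oligo") > 100
    with pytest.raises(ConfigurationError, match="preset"):
        species_phenotype("rattus")


def test_standard_plate_layout_counts():
    run, truth = generate_plate(GeneratorConfig(n_experiments=3, seed=4))
    assert len(run.traces) == 3 * 24
    assert len(run.background_wells()) == 12
    assert len(truth.experiment_effects) == 3
    assert all(c > 0 for c in truth.sperm_counts.values())
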