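"""Window arithmetic of the bioenergetic panel and modulator responses.

Each derived quantity is checked against a naive reimplementation working
directly on the cycle lists, plus hand-computed examples and the exact
algebraic identities of the panel.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import flat_trace, make_normalized, random_trace
from fluxcap.errors import UndefinedPanelError, UsageError, ValidationError
from fluxcap.parameters import (basal_respiration, build_panel,
                                build_responses, condition_percent_change,
                                glycolysis_panel, maximal_and_spare,
                                ocr_ecar_ratio, proton_leak_and_atp_linked,
                                response_percent, window_aggregate)
from fluxcap.plate import CycleWindows


# ---------------------------------------------------------------- oracles

def naive(trace, cycles, signal, fn):
    """Direct aggregation from the cycle list, no shared code path."""
    vals = [trace.signal(signal)[list(trace.cycle_index).index(c)]
            for c in cycles]
    return fn(vals)


def naive_basal(trace):
    base = sum(naive(trace, [c], "OCR", sum) for c in (2, 3, 4)) / 3
    ar = sum(naive(trace, [c], "OCR", sum) for c in (8, 9)) / 2
    return base - ar


def naive_leak(base_tr, oligo_tr):
    basal = naive_basal(base_tr)
    t = sum(naive(oligo_tr, [c], "OCR", sum) for c in (5, 6, 7)) / 3
    a = sum(naive(oligo_tr, [c], "OCR", sum) for c in (8, 9)) / 2
    return 100 * (t - a) / basal


def naive_maximal(fccp_tr, basal):
    t = max(naive(fccp_tr, [c], "OCR", sum) for c in (5, 6, 7))
    a = sum(naive(fccp_tr, [c], "OCR", sum) for c in (8, 9)) / 2
    return 100 * (t - a) / basal


def naive_reserve(base_tr, oligo_tr):
    g = sum(naive(base_tr, [c], "ECAR", sum) for c in (2, 3, 4)) / 3
    peak = max(naive(oligo_tr, [c], "ECAR", sum) for c in (5, 6, 7))
    return 100 * (peak - g) / g


def naive_response(trace, signal, mode):
    base = sum(naive(trace, [c], signal, sum) for c in (2, 3, 4)) / 3
    vals = [naive(trace, [c], signal, sum) for c in (5, 6, 7)]
    t = {"mean": sum(vals) / 3, "max": max(vals), "min": min(vals)}[mode]
    if signal == "OCR":
        a = sum(naive(trace, [c], "OCR", sum) for c in (8, 9)) / 2
        base, t = base - a, t - a
    return 100 * t / base


# ------------------------------------------------------------- aggregates

def test_window_aggregate_modes(windows):
    tr = make_normalized("w", [0, 10, 12, 14, 30, 45, 40, 5, 5],
                         [0, 20, 20, 20, 30, 45, 40, 25, 25])
    assert window_aggregate(tr, windows, "baseline", "mean").ocr_value == 12
    assert window_aggregate(tr, windows, "treatment", "max").ecar_value == 45
    const = make_normalized("c", [7] * 9, [3] * 9)
    for mode in ("mean", "max", "min"):
        agg = window_aggregate(const, windows, "treatment", mode)
        assert agg.ocr_value == 7 and agg.ecar_value == 3


def test_window_aggregate_missing_cycle_raises(windows):
    tr = make_normalized("w", list(range(8)), list(range(8)), n_cycles=8)
    with pytest.raises(ValidationError, match="9"):
        window_aggregate(tr, windows, "ar", "mean")
    with pytest.raises(UsageError):
        window_aggregate(tr, windows, "baseline", "median")


# ------------------------------------------------------ panel quantities

def test_basal_respiration_examples(windows):
    assert basal_respiration(flat_trace("w", 100, 100, 5), windows).value \
        == pytest.approx(95.0)
    assert basal_respiration(flat_trace("w", 50, 50, 50), windows).value \
        == pytest.approx(0.0)


def test_basal_respiration_fallback_without_ar_window(windows):
    tr = make_normalized("w", [100] * 7, [20] * 7, n_cycles=7)
    res = basal_respiration(tr, windows)
    assert res.value == pytest.approx(100.0)
    assert not res.ar_corrected


def test_proton_leak_hand_example(windows):
    """baseline 100, oligo(5-7) 40, A+R 5 -> basal 95, leak 36.84%."""
    base = flat_trace("b", 100, 100, 5)
    oligo = flat_trace("o", 100, 40, 5)
    leak, atp = proton_leak_and_atp_linked(base, oligo, windows)
    assert leak == pytest.approx(100 * 35 / 95)
    assert atp == pytest.approx(100 - 100 * 35 / 95)


def test_full_coupling_when_oligo_equals_ar(windows):
    base = flat_trace("b", 100, 100, 5)
    oligo = flat_trace("o", 100, 5, 5)
    leak, atp = proton_leak_and_atp_linked(base, oligo, windows)
    assert leak == pytest.approx(0.0)
    assert atp == pytest.approx(100.0)


def test_nonpositive_basal_is_undefined(windows):
    base = flat_trace("b", 5, 5, 5)
    oligo = flat_trace("o", 100, 40, 5)
    with pytest.raises(UndefinedPanelError):
        proton_leak_and_atp_linked(base, oligo, windows)
    with pytest.raises(UndefinedPanelError):
        maximal_and_spare(oligo, windows, 0.0)


def test_maximal_and_spare_hand_example(windows):
    """FCCP max 800, A+R 5, basal 95 -> maximal 836.8%, spare 736.8%."""
    fccp = make_normalized("f", [100] * 4 + [700, 800, 750] + [5, 5],
                           [20] * 9)
    maximal, spare = maximal_and_spare(fccp, windows, 95.0)
    assert maximal == pytest.approx(100 * 795 / 95)
    assert spare == pytest.approx(maximal - 100)


def test_glycolysis_hand_example(windows):
    """baseline ECAR 18.9, oligo peak 31.7 -> reserve 67.7%."""
    base = flat_trace("b", 100, 100, 5, ecar_baseline=18.9)
    oligo = make_normalized("o", [100] * 9,
                            [18.9] * 4 + [30.0, 31.7, 29.5] + [20, 20])
    gly, reserve = glycolysis_panel(base, oligo, windows)
    assert gly == pytest.approx(18.9)
    assert reserve == pytest.approx(100 * (31.7 - 18.9) / 18.9)


def test_ocr_ecar_ratio_and_homogeneity(windows):
    tr = flat_trace("w", 300, 300, 5, ecar_baseline=60.0)
    assert ocr_ecar_ratio(tr, windows) == pytest.approx(5.0)
    scaled = make_normalized("w", tr.ocr * 7.3, tr.ecar * 7.3)
    assert ocr_ecar_ratio(scaled, windows) == pytest.approx(5.0)


# -------------------------------------------------------------- responses

def test_response_hand_example(windows):
    """OCR baseline 100, oligo(5-7) 40, A+R 5 -> 36.8% of baseline."""
    tr = flat_trace("w", 100, 40, 5)
    rv = response_percent(tr, windows, "OCR", "oligo")
    assert rv.percent_of_baseline == pytest.approx(100 * 35 / 95)
    assert rv.delta_percent == pytest.approx(rv.percent_of_baseline - 100)
    assert rv.ar_corrected


def test_response_identity_when_treatment_equals_baseline(windows):
    tr = flat_trace("w", 80, 80, 5, ecar_baseline=30, ecar_treat=30)
    for signal in ("OCR", "ECAR"):
        rv = response_percent(tr, windows, signal, "baseline")
        assert rv.percent_of_baseline == pytest.approx(100.0)
        assert rv.delta_percent == pytest.approx(0.0)


def test_extremum_convention_selects_max_and_min(windows):
    tr = make_normalized("w", [100] * 9,
                         [30] * 4 + [40, 55, 45] + [35, 35])
    mean_rv = response_percent(tr, windows, "ECAR", "oligo", "mean")
    max_rv = response_percent(tr, windows, "ECAR", "oligo", "extremum")
    assert max_rv.percent_of_baseline == pytest.approx(100 * 55 / 30)
    assert mean_rv.percent_of_baseline < max_rv.percent_of_baseline
    min_rv = response_percent(tr, windows, "ECAR", "2dog", "extremum")
    assert min_rv.percent_of_baseline == pytest.approx(100 * 40 / 30)


def test_ar_constant_shift_invariance(windows):
    """Adding a constant to every OCR cycle leaves the corrected percent
    response unchanged (the A+R correction cancels it)."""
    rng = np.random.default_rng(3)
    tr = make_normalized("w", np.r_[rng.normal(100, 10, 4),
                                    rng.normal(40, 10, 3),
                                    rng.normal(5, 1, 2)],
                         rng.uniform(10, 50, 9))
    base = response_percent(tr, windows, "OCR", "oligo").percent_of_baseline
    for c in (-30.0, 17.5, 250.0):
        shifted = make_normalized("w", tr.ocr + c, tr.ecar)
        got = response_percent(shifted, windows, "OCR", "oligo")
        assert got.percent_of_baseline == pytest.approx(base, rel=1e-9)


def test_nonpositive_corrected_baseline_flagged(windows):
    tr = flat_trace("w", 5, 40, 10)   # baseline below the A+R floor
    with pytest.raises(UndefinedPanelError):
        response_percent(tr, windows, "OCR", "oligo")


def test_condition_percent_change_examples():
    assert round(condition_percent_change(315, 231, "decrease")) == 27
    assert round(condition_percent_change(18.9, 25.7, "increase")) == 36
    assert condition_percent_change(42.0, 42.0, "decrease") == 0.0
    with pytest.raises(UndefinedPanelError):
        condition_percent_change(0.0, 5.0, "decrease")


# --------------------------------------------------- brute-force parity

@settings(max_examples=150, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_brute_force_oracle_parity(seed):
    """Every panel quantity equals the naive cycle-list reimplementation."""
    rng = np.random.default_rng(seed)
    windows = CycleWindows()
    base = make_normalized("b", rng.uniform(50, 150, 9), rng.uniform(10, 50, 9))
    oligo = make_normalized("o", rng.uniform(5, 80, 9), rng.uniform(10, 60, 9))
    fccp = make_normalized("f", rng.uniform(100, 900, 9), rng.uniform(10, 50, 9))
    basal = basal_respiration(base, windows).value
    assert basal == pytest.approx(naive_basal(base), rel=1e-12)
    if basal > 0:
        leak, atp = proton_leak_and_atp_linked(base, oligo, windows)
        assert leak == pytest.approx(naive_leak(base, oligo), rel=1e-12)
        assert leak + atp == pytest.approx(100.0, abs=1e-12)
        maximal, spare = maximal_and_spare(fccp, windows, basal)
        assert maximal == pytest.approx(naive_maximal(fccp, basal), rel=1e-12)
        assert spare == pytest.approx(maximal - 100.0, abs=1e-12)
    gly, reserve = glycolysis_panel(base, oligo, windows)
    assert reserve == pytest.approx(naive_reserve(base, oligo), rel=1e-12)
    for signal, mode in (("OCR", "mean"), ("ECAR", "mean")):
        try:
            rv = response_percent(base, windows, signal, "oligo", "mean")
        except UndefinedPanelError:
            continue
        assert rv.percent_of_baseline == pytest.approx(
            naive_response(base, signal, mode), rel=1e-12)
        assert rv.delta_percent == pytest.approx(
            rv.percent_of_baseline - 100.0, abs=1e-12)


@settings(max_examples=60, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_aggregation_mode_ordering(seed):
    rng = np.random.default_rng(seed)
    tr = random_trace(rng)
    windows = CycleWindows()
    for signal in ("OCR", "ECAR"):
        lo = window_aggregate(tr, windows, "treatment", "min")
        mid = window_aggregate(tr, windows, "treatment", "mean")
        hi = window_aggregate(tr, windows, "treatment", "max")
        v = {"OCR": "ocr_value", "ECAR": "ecar_value"}[signal]
        assert getattr(lo, v) <= getattr(mid, v) <= getattr(hi, v)


# ----------------------------------------------------------- assembly

def test_panel_identities_on_generated_run(small_run):
    run, _ = small_run
    from fluxcap.normalize import background_correct, normalize_per_sperm
    normalized = normalize_per_sperm(background_correct(run))
    panel = build_panel(normalized, run.annotations, run.windows)
    ok = panel.dropna(subset=["proton_leak_pct"])
    np.testing.assert_allclose(
        ok.proton_leak_pct + ok.atp_linked_pct, 100.0, atol=1e-9)
    ok = panel.dropna(subset=["maximal_respiration_pct"])
    np.testing.assert_allclose(
        ok.maximal_respiration_pct - ok.spare_capacity_pct, 100.0, atol=1e-9)
    # one row per baseline well
    n_baseline = sum(1 for a in run.annotations.values()
                     if a.treatment is not None and a.treatment.value == "baseline")
    assert len(panel) == n_baseline


def test_responses_long_table_structure(small_run):
    run, _ = small_run
    from fluxcap.normalize import background_correct, normalize_per_sperm
    normalized = normalize_per_sperm(background_correct(run))
    resp = build_responses(normalized, run.annotations, run.windows)
    assert set(resp.signal) == {"OCR", "ECAR"}
    assert "ar" in set(resp.treatment)
    ar_rows = resp[resp.treatment == "ar"]
    assert set(ar_rows.signal) == {"ECAR"}
    np.testing.assert_allclose(resp.delta_percent,
                               resp.percent_of_baseline - 100, atol=1e-12)
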