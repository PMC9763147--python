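"""LRTs, residual-based family choice, marginal-means contrasts, summaries."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from fluxcap.errors import UsageError
from fluxcap.stats import (ModelSpec, choose_family, emm_contrasts,
                           fit_lmm_log10, lrt, summarize)

SPEC = ModelSpec("value", ("condition",))


def lmm_frame(rng, n_exp=6, n_well=8, b_cap=-0.15, sd_u=0.25, sd_e=0.35):
    rows = []
    for e in range(n_exp):
        u = rng.normal(0, sd_u)
        for cond, b in (("NC", 0.0), ("CAP", b_cap)):
            for v in 10 ** (2.5 + b + u + rng.normal(0, sd_e, n_well)):
                rows.append((f"E{e}", cond, float(v)))
    return pd.DataFrame(rows, columns=["experiment_id", "condition", "value"])


def gamma_frame(rng, n_exp=6, n_well=8, k=2.0):
    rows = []
    for e in range(n_exp):
        u = rng.normal(0, 0.001)
        for cond, b in (("NC", 0.0), ("CAP", 0.004)):
            eta = 0.01 + b + u
            for v in rng.gamma(k, 1.0 / (eta * k), n_well):
                rows.append((f"E{e}", cond, float(v)))
    return pd.DataFrame(rows, columns=["experiment_id", "condition", "value"])


# ------------------------------------------------------------------- LRT

def test_lrt_of_identical_models_is_null():
    rng = np.random.default_rng(0)
    df = lmm_frame(rng)
    fit = fit_lmm_log10(df, SPEC)
    res = lrt(fit, fit)
    assert res.chi2 == 0.0 and res.df == 0 and res.p_value == 1.0


def test_lrt_rejects_non_nested_models():
    rng = np.random.default_rng(0)
    df = lmm_frame(rng).assign(batch=lambda d: d.experiment_id)
    full = fit_lmm_log10(df, ModelSpec("value", ("condition",)))
    other = fit_lmm_log10(df, ModelSpec("value", ("batch",)))
    with pytest.raises(UsageError, match="nested"):
        lrt(full, other)


def test_lrt_power_grows_with_sample_size():
    """With a real effect, the median p-value falls as wells accumulate."""
    med = []
    for n_well in (3, 10, 30):
        ps = []
        rng = np.random.default_rng(100 + n_well)
        for _ in range(25):
            df = lmm_frame(rng, n_well=n_well, b_cap=-0.08, sd_e=0.2)
            full = fit_lmm_log10(df, SPEC)
            red = fit_lmm_log10(df, ModelSpec("value", ()))
            ps.append(lrt(full, red).p_value)
        med.append(np.median(ps))
    assert med[0] > med[-1]
    assert med[-1] < 0.01


def test_naive_pooling_inflates_with_experiment_sd_but_mixed_does_not():
    """When condition is confounded with experiment, raising the
    between-experiment SD drives a pooled t-test's false-positive rate up;
    the random-intercept LRT's rate stays flat (elevated only by the small
    number of experiments, not by the experiment variance)."""
    from scipy import stats as sps
    from fluxcap.simulate import GeneratorConfig, generate_null_dataset

    def rates(sd, n=250, n_exp=8):
        cfg = GeneratorConfig(n_experiments=n_exp, wells_per_treatment=5,
                              treatments=("baseline",),
                              condition_means={"NC": (300.0, 20.0),
                                               "CAP": (300.0, 20.0)},
                              between_experiment_sd=sd, seed=99)
        half = [f"E{i}" for i in range(1, n_exp // 2 + 1)]
        naive = mixed = 0
        for df in generate_null_dataset(cfg, n):
            df = df.assign(condition=np.where(
                df.experiment_id.isin(half), "NC", "CAP"))
            a = np.log10(df[df.condition == "NC"]["value"])
            b = np.log10(df[df.condition == "CAP"]["value"])
            naive += sps.ttest_ind(a, b).pvalue < 0.05
            full = fit_lmm_log10(df, SPEC)
            red = fit_lmm_log10(df, ModelSpec("value", ()))
            mixed += lrt(full, red).p_value < 0.05
        return naive / n, mixed / n

    naive_lo, mixed_lo = rates(0.05)
    naive_hi, mixed_hi = rates(0.6)
    assert naive_hi > naive_lo + 0.15        # inflation grows with SD
    assert mixed_hi <= mixed_lo + 0.05       # mixed model stays flat
    assert mixed_hi < naive_hi / 2


# --------------------------------------------------------- family choice

def test_family_choice_prefers_true_generating_family():
    spec = SPEC
    rng = np.random.default_rng(11)
    gauss_votes = sum(
        choose_family(lmm_frame(rng, n_well=12, sd_e=0.5), spec).family
        == "gaussian_log10" for _ in range(15))
    gamma_votes = sum(
        choose_family(gamma_frame(rng), spec).family == "gamma_inverse"
        for _ in range(15))
    assert gauss_votes >= 14
    assert gamma_votes >= 14


def test_family_choice_reports_both_fits():
    rng = np.random.default_rng(2)
    choice = choose_family(lmm_frame(rng), SPEC)
    assert set(choice.fits) == {"gaussian_log10", "gamma_inverse"}
    assert set(choice.shapiro_w) == {"gaussian_log10", "gamma_inverse"}


# ------------------------------------------------------------- contrasts

def test_contrast_counts_match_pair_formula():
    rng = np.random.default_rng(4)
    rows = []
    for e in range(5):
        u = rng.normal(0, 0.2)
        for i, t in enumerate(["baseline", "oligo", "fccp",
                               "2dog", "oxamate", "ar"]):
            for v in 10 ** (2 + 0.05 * i + u + rng.normal(0, 0.2, 3)):
                rows.append((f"E{e}", t, float(v)))
    df = pd.DataFrame(rows, columns=["experiment_id", "treatment", "value"])
    fit = fit_lmm_log10(df, ModelSpec("value", ("treatment",)))
    cs = emm_contrasts(fit, "treatment")
    assert len(cs) == 15                     # C(6,2)
    assert all(c.p_adjusted >= c.p_unadjusted - 1e-12 for c in cs)
    two = fit_lmm_log10(lmm_frame(rng), SPEC)
    assert len(emm_contrasts(two, "condition")) == 1


def test_contrasts_invariant_to_level_relabeling():
    rng = np.random.default_rng(8)
    df = lmm_frame(rng)
    fit1 = fit_lmm_log10(df, SPEC)
    relabeled = df.assign(condition=df.condition.map(
        {"NC": "zz_nc", "CAP": "aa_cap"}))
    fit2 = fit_lmm_log10(relabeled, SPEC)
    c1 = emm_contrasts(fit1, "condition")[0]
    c2 = emm_contrasts(fit2, "condition")[0]
    assert abs(c1.estimate_link_scale) == pytest.approx(
        abs(c2.estimate_link_scale), rel=1e-8)
    assert c1.p_adjusted == pytest.approx(c2.p_adjusted, rel=1e-6)


def test_familywise_error_controlled_under_equal_means():
    """Tukey adjustment keeps the probability of any false positive among
    C(4,2)=6 contrasts at or below ~alpha."""
    rng = np.random.default_rng(17)
    fwer = 0
    n = 400
    for _ in range(n):
        rows = []
        for e in range(5):
            u = rng.normal(0, 0.2)
            for t in "abcd":
                for v in 10 ** (2 + u + rng.normal(0, 0.2, 4)):
                    rows.append((f"E{e}", t, float(v)))
        df = pd.DataFrame(rows, columns=["experiment_id", "treatment", "value"])
        fit = fit_lmm_log10(df, ModelSpec("value", ("treatment",)))
        cs = emm_contrasts(fit, "treatment")
        fwer += any(c.p_adjusted < 0.05 for c in cs)
    assert fwer / n < 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n)


def test_single_level_factor_yields_no_contrasts():
    rng = np.random.default_rng(1)
    df = lmm_frame(rng).assign(batch="only")
    fit = fit_lmm_log10(df, ModelSpec("value", ("batch",)))
    assert emm_contrasts(fit, "batch") == []


# -------------------------------------------------------------- summaries

def test_summary_textbook_values():
    df = pd.DataFrame({"experiment_id": ["E1", "E2", "E3"],
                       "condition": ["NC"] * 3,
                       "value": [1.0, 2.0, 3.0]})
    row = summarize(df, ["condition"], "value").iloc[0]
    assert row["mean"] == pytest.approx(2.0)
    assert row["sd"] == pytest.approx(1.0)
    assert row["n_experiments"] == 3


def test_summary_single_observation_flagged():
    df = pd.DataFrame({"experiment_id": ["E1"], "condition": ["NC"],
                       "value": [5.0]})
    row = summarize(df, ["condition"], "value").iloc[0]
    assert row["sd"] == 0.0 and bool(row["sd_undefined"])


def test_summary_ci_close_to_bootstrap_percentile():
    rng = np.random.default_rng(23)
    vals = rng.lognormal(3.0, 0.3, 60)
    df = pd.DataFrame({"experiment_id": [f"E{i % 6}" for i in range(60)],
                       "condition": ["NC"] * 60, "value": vals})
    row = summarize(df, ["condition"], "value").iloc[0]
    boots = np.array([rng.choice(vals, 60).mean() for _ in range(4000)])
    half = (np.percentile(boots, 97.5) - np.percentile(boots, 2.5)) / 2
    assert row["ci_wells"] == pytest.approx(half, rel=0.10)
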