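"""End-to-end orchestration: simulate/load -> normalize -> panel -> stats.

A run is driven by one YAML (or dict) config and writes a self-contained
output directory: stage CSVs, fitted-model JSON, a markdown report with
cohort tables and condition percent-change lines, and a manifest recording
config hash, input digests, seed, package versions and stage status.
Outputs other than the manifest are byte-deterministic for a fixed config.

Config schema (keys under the root):

    seed: int                     # overrides simulate seed
    out_dir: path
    simulate:                     # either this ...
      species: spicilegus|musculus
      <GeneratorConfig field overrides>
    inputs:                       # ... or this
      traces: traces.csv
      layout: layout.csv
    atp:
      simulate: true              # or {standards: csv, samples: csv}
    stats:
      adjustment: tukey|none
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atp import analyze_atp_tables
from .errors import ConfigurationError, FluxcapError
from .io import read_plate_kinetics, write_plate_kinetics
from .normalize import background_correct, normalize_per_sperm
from .parameters import (PANEL_QUANTITIES, build_panel, build_responses,
                         condition_percent_change, panel_long)
from .simulate import (AtpAssayConfig, GeneratorConfig, generate_atp_tables,
                       generate_plate, species_phenotype)
from .stats import (GAMMA_INVERSE, GAUSSIAN_LOG10, ModelSpec, choose_family,
                    contrasts_frame, emm_contrasts, fit_family, lrt,
                    summarize)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_generator_config(block: dict, seed: int | None) -> GeneratorConfig:
    block = dict(block)
    species = block.pop("species", "spicilegus")
    base = species_phenotype(species)
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(block) - known
    if unknown:
        raise ConfigurationError(f"simulate block: unknown key(s) {sorted(unknown)}")
    if seed is not None:
        block["seed"] = int(seed)
    for key in ("condition_means",):
        if key in block:
            block[key] = {k: tuple(v) for k, v in block[key].items()}
    return dataclasses.replace(base, **block)


def _stats_for_quantity(data: pd.DataFrame, response: str,
                        fixed: tuple[str, ...], adjustment: str,
                        lrt_rows: list, contrast_rows: list, fits: dict) -> None:
    spec = ModelSpec(response=response, fixed=fixed)
    sub = data.dropna(subset=[response])
    sub = sub[sub[response] > 0]
    if sub.empty or sub["experiment_id"].nunique() < 2:
        return
    choice = choose_family(sub, spec)
    family = choice.family
    full = choice.fits[family]
    fits[response] = {
        "family": family,
        "shapiro_w": choice.shapiro_w,
        "coefficients": {k: list(v) for k, v in full.coefficients.items()},
        "random_intercept_variance": full.random_intercept_variance,
        "residual_dispersion": full.residual_dispersion,
        "log_likelihood": full.log_likelihood,
        "n_obs": full.n_obs, "n_groups": full.n_groups,
        "converged": full.converged, "method": full.method,
    }
    for term in fixed:
        reduced_fixed = tuple(t for t in fixed if t != term and term not in t.split(":"))
        if ":" in term:
            reduced_fixed = tuple(t for t in fixed if t != term)
        reduced = fit_family(sub, spec.with_fixed(reduced_fixed).with_family(family))
        res = lrt(full, reduced)
        lrt_rows.append({"response": response, "term": term,
                         "family": family, "chi2": res.chi2, "df": res.df,
                         "p_value": res.p_value})
    for factor in [t for t in fixed if ":" not in t]:
        for c in emm_contrasts(full, factor, adjustment=adjustment):
            contrast_rows.append({"response": response, "factor": factor,
                                  "level_a": c.pair[0], "level_b": c.pair[1],
                                  "estimate_link_scale": c.estimate_link_scale,
                                  "std_error": c.std_error,
                                  "statistic": c.statistic, "df": c.df,
                                  "p_adjusted": c.p_adjusted,
                                  "adjustment": c.adjustment})


def _fmt_table(df: pd.DataFrame, floatfmt: str = "{:.1f}") -> str:
    """Plain markdown table without extra dependencies."""
    cols = list(df.columns)
    def fmt(v):
        if isinstance(v, float):
            return floatfmt.format(v)
        return str(v)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines)


def _report(out: Path, panel_summary: pd.DataFrame,
            response_summary: pd.DataFrame, changes: list[str]) -> None:
    parts = ["# Extracellular flux analysis report", ""]
    parts += ["## Bioenergetic parameter panel (cohort summary)", "",
              _fmt_table(panel_summary), ""]
    parts += ["## Modulator responses, % of baseline (cohort summary)", "",
              _fmt_table(response_summary), ""]
    parts += ["## Condition effects on basal rates", ""]
    parts += [f"- {line}" for line in changes]
    parts.append("")
    (out / "report.md").write_text("\n".join(parts))


def run_pipeline(config: dict | str | Path,
                 out_dir: str | Path | None = None) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Raises on the first failing stage after recording it in the manifest.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ConfigurationError("pipeline config must be a mapping")
    out = Path(out_dir or config.get("out_dir", "fluxcap_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "versions": {"fluxcap": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": {},
        "stages": [],
    }

    def stage(name: str):
        manifest["stages"].append({"name": name, "status": "running"})

    def done():
        manifest["stages"][-1]["status"] = "ok"

    try:
        stage("acquire")
        if "simulate" in config:
            gen = _build_generator_config(config["simulate"] or {}, seed)
            run, _truth = generate_plate(gen)
            write_plate_kinetics(run, out / "traces.csv", out / "layout.csv")
            manifest["inputs"]["traces"] = _digest(out / "traces.csv")
            manifest["inputs"]["layout"] = _digest(out / "layout.csv")
        elif "inputs" in config:
            inputs = config["inputs"] or {}
            for key in ("traces", "layout"):
                if key not in inputs:
                    raise ConfigurationError(f"config inputs: missing key {key!r}")
            run = read_plate_kinetics(inputs["traces"], inputs["layout"])
            manifest["inputs"]["traces"] = _digest(Path(inputs["traces"]))
            manifest["inputs"]["layout"] = _digest(Path(inputs["layout"]))
        else:
            raise ConfigurationError(
                "config must contain a 'simulate' or an 'inputs' block")
        done()

        stage("normalize")
        corrected = background_correct(run)
        normalized = normalize_per_sperm(corrected)
        rows = []
        for well_id in sorted(normalized):
            tr = normalized[well_id]
            for i, c in enumerate(tr.cycle_index):
                rows.append((well_id, int(c), tr.ocr[i], tr.ecar[i]))
        pd.DataFrame(rows, columns=["well_id", "cycle", "ocr", "ecar"]).to_csv(
            out / "normalized.csv", index=False)
        done()

        stage("panel")
        panel = build_panel(normalized, run.annotations, run.windows)
        panel.to_csv(out / "panel.csv", index=False)
        panel_long(panel).to_csv(out / "panel_long.csv", index=False)
        done()

        stage("responses")
        responses = build_responses(normalized, run.annotations, run.windows)
        responses.to_csv(out / "responses.csv", index=False)
        done()

        stage("stats")
        adjustment = (config.get("stats") or {}).get("adjustment", "tukey")
        lrt_rows: list = []
        contrast_rows: list = []
        fits: dict = {}
        for q in PANEL_QUANTITIES:
            _stats_for_quantity(panel, q, ("condition",), adjustment,
                                lrt_rows, contrast_rows, fits)
        resp_mod = responses[responses["treatment"] != "baseline"].rename(
            columns={"percent_of_baseline": "response_pct"})
        for signal in ("OCR", "ECAR"):
            sub = resp_mod[resp_mod["signal"] == signal].copy()
            sub = sub.rename(columns={"response_pct": f"{signal}_response_pct"})
            _stats_for_quantity(
                sub, f"{signal}_response_pct",
                ("condition", "treatment", "condition:treatment"),
                adjustment, lrt_rows, contrast_rows, fits)
        pd.DataFrame(lrt_rows).to_csv(out / "lrt.csv", index=False)
        pd.DataFrame(contrast_rows).to_csv(out / "contrasts.csv", index=False)
        (out / "fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))
        done()

        if "atp" in config:
            stage("atp")
            atp_cfg = config["atp"] or {}
            if atp_cfg.get("simulate"):
                standards, samples, _ = generate_atp_tables(
                    AtpAssayConfig(seed=seed if seed is not None else 20221219))
            else:
                standards = pd.read_csv(atp_cfg["standards"])
                samples = pd.read_csv(atp_cfg["samples"])
            analyze_atp_tables(standards, samples).to_csv(
                out / "atp.csv", index=False)
            done()

        stage("report")
        panel_summary = summarize(panel_long(panel),
                                  ["quantity", "condition"], "value")
        response_summary = summarize(
            responses[responses["treatment"] != "baseline"],
            ["signal", "treatment", "condition"], "percent_of_baseline")
        changes = []
        cond_means = (panel.groupby("condition")[["basal_respiration",
                                                  "basal_glycolysis"]]
                      .mean(numeric_only=True))
        if {"NC", "CAP"} <= set(cond_means.index):
            dec = condition_percent_change(
                cond_means.loc["NC", "basal_respiration"],
                cond_means.loc["CAP", "basal_respiration"], "decrease")
            inc = condition_percent_change(
                cond_means.loc["NC", "basal_glycolysis"],
                cond_means.loc["CAP", "basal_glycolysis"], "increase")
            changes.append(
                f"Capacitating incubation decreased basal respiration by "
                f"{dec:.0f}% (cohort means "
                f"{cond_means.loc['NC', 'basal_respiration']:.1f} -> "
                f"{cond_means.loc['CAP', 'basal_respiration']:.1f} "
                f"amol O2 min^-1 sperm^-1).")
            changes.append(
                f"Capacitating incubation changed basal glycolysis by "
                f"{inc:+.0f}% (cohort means "
                f"{cond_means.loc['NC', 'basal_glycolysis']:.1f} -> "
                f"{cond_means.loc['CAP', 'basal_glycolysis']:.1f} "
                f"nano-pH min^-1 sperm^-1).")
        _report(out, panel_summary, response_summary, changes)
        done()
    except Exception as exc:
        if manifest["stages"]:
            manifest["stages"][-1]["status"] = f"failed: {exc}"
        manifest["finished_utc"] = datetime.now(timezone.utc).isoformat()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["finished_utc"] = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
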