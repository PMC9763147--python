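"""Reading and writing plate kinetics, layouts and derived tables.

The package defines its own plain CSV dialects (UTF-8, "." decimal):

* traces:  ``well_id,cycle,time_min,ocr_raw,ecar_raw``
* layout:  ``well_id,experiment_id,condition,treatment,sperm_count,is_background``
  with ``condition`` in {NC, CAP}, ``treatment`` in
  {baseline, oligo, fccp, 2dog, oxamate} and ``is_background`` in {0, 1};
  background rows leave condition/treatment/sperm_count empty.

Vendor instrument exports are deliberately not parsed here; a converter to
these dialects is the caller's responsibility.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ValidationError
from .plate import (Condition, CycleWindows, PlateRun, Treatment,
                    WellAnnotation, WellTrace)

TRACE_COLUMNS = ["well_id", "cycle", "time_min", "ocr_raw", "ecar_raw"]
LAYOUT_COLUMNS = ["well_id", "experiment_id", "condition", "treatment",
                  "sperm_count", "is_background"]


def _read_csv(path: str | Path, required: list[str], optional: set[str] = frozenset()
              ) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"well_id": str, "experiment_id": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns and c not in optional]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    return df


def read_traces(path: str | Path) -> dict[str, WellTrace]:
    """Parse the traces CSV into per-well kinetic traces.

    If the ``cycle`` column is absent but ``time_min`` is present, cycles
    are renumbered 1-based per well in time order.
    """
    df = _read_csv(Path(path), TRACE_COLUMNS, optional={"cycle"})
    if "cycle" not in df.columns:
        df = df.sort_values(["well_id", "time_min"], kind="stable").copy()
        df["cycle"] = df.groupby("well_id").cumcount() + 1
    dup = df.duplicated(subset=["well_id", "cycle"])
    if dup.any():
        pairs = df.loc[dup, ["well_id", "cycle"]].itertuples(index=False)
        raise ConsistencyError(
            "duplicate (well, cycle) rows: " +
            ", ".join(f"({w}, {c})" for w, c in pairs))
    for col in ("time_min", "ocr_raw", "ecar_raw"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "well_id"].unique().tolist()
            raise FormatError(f"column {col}: non-numeric values in wells {bad}")
        df[col] = vals
    traces: dict[str, WellTrace] = {}
    for well_id, sub in df.groupby("well_id", sort=True):
        sub = sub.sort_values("cycle")
        traces[str(well_id)] = WellTrace(
            well_id=str(well_id),
            cycle_index=sub["cycle"].to_numpy(dtype=int),
            time_min=sub["time_min"].to_numpy(dtype=float),
            ocr=sub["ocr_raw"].to_numpy(dtype=float),
            ecar=sub["ecar_raw"].to_numpy(dtype=float),
        )
    return traces


def _parse_condition(token: object) -> Condition:
    try:
        return Condition(str(token).strip())
    except ValueError:
        raise FormatError(
            f"unknown condition {token!r} (expected NC or CAP)") from None


def _parse_treatment(token: object) -> Treatment:
    try:
        return Treatment(str(token).strip())
    except ValueError:
        raise FormatError(
            f"unknown treatment {token!r} (expected one of "
            f"{[t.value for t in Treatment]})") from None


def read_layout(path: str | Path) -> dict[str, WellAnnotation]:
    """Parse the layout CSV into per-well annotations."""
    df = _read_csv(Path(path), LAYOUT_COLUMNS)
    if df["well_id"].duplicated().any():
        dups = df.loc[df["well_id"].duplicated(), "well_id"].tolist()
        raise ConsistencyError(f"duplicate wells in layout: {dups}")
    annotations: dict[str, WellAnnotation] = {}
    for row in df.itertuples(index=False):
        is_bg = bool(int(row.is_background))
        if is_bg:
            ann = WellAnnotation(well_id=str(row.well_id),
                                 experiment_id=str(row.experiment_id),
                                 is_background=True)
        else:
            count = pd.to_numeric(pd.Series([row.sperm_count]), errors="coerce").iloc[0]
            if pd.isna(count) or count <= 0 or int(count) != count:
                raise ValidationError(
                    f"well {row.well_id}: sperm_count must be a positive integer, "
                    f"got {row.sperm_count!r}")
            ann = WellAnnotation(
                well_id=str(row.well_id),
                experiment_id=str(row.experiment_id),
                condition=_parse_condition(row.condition),
                treatment=_parse_treatment(row.treatment),
                sperm_count=int(count),
                is_background=False)
        annotations[ann.well_id] = ann
    return annotations


def read_plate_kinetics(path: str | Path, layout_path: str | Path,
                        windows: CycleWindows | None = None,
                        run_id: str | None = None) -> PlateRun:
    """Read and cross-validate a traces file and its plate layout.

    Raises :class:`FormatError` for malformed files, :class:`ConsistencyError`
    when the two files disagree on the set of wells, and
    :class:`ValidationError` for invariant violations (duplicate cycles,
    non-positive sperm counts, non-finite rates).
    """
    traces = read_traces(path)
    annotations = read_layout(layout_path)
    t, a = set(traces), set(annotations)
    if t != a:
        raise ConsistencyError(
            f"wells in traces but not layout: {sorted(t - a)}; "
            f"wells in layout but not traces: {sorted(a - t)}")
    run = PlateRun(run_id=run_id or Path(path).stem,
                   traces=traces, annotations=annotations,
                   windows=windows or CycleWindows())
    for exp in run.experiment_ids:
        if not run.background_wells(exp):
            raise ValidationError(f"experiment {exp}: no background wells")
    return run


def traces_frame(run: PlateRun) -> pd.DataFrame:
    """Long-format traces table in the documented column order."""
    rows = []
    for well_id in run.well_ids:
        tr = run.traces[well_id]
        for i in range(tr.n_cycles):
            rows.append((well_id, int(tr.cycle_index[i]), tr.time_min[i],
                         tr.ocr[i], tr.ecar[i]))
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def layout_frame(run: PlateRun) -> pd.DataFrame:
    rows = []
    for well_id in run.well_ids:
        a = run.annotations[well_id]
        rows.append((well_id, a.experiment_id,
                     a.condition.value if a.condition else "",
                     a.treatment.value if a.treatment else "",
                     a.sperm_count if a.sperm_count is not None else "",
                     int(a.is_background)))
    return pd.DataFrame(rows, columns=LAYOUT_COLUMNS)


def write_plate_kinetics(run: PlateRun, traces_path: str | Path,
                         layout_path: str | Path) -> None:
    traces_frame(run).to_csv(traces_path, index=False)
    layout_frame(run).to_csv(layout_path, index=False)


def write_tidy_tables(run: PlateRun, panel: pd.DataFrame | None,
                      out_dir: str | Path) -> list[Path]:
    """Write the run (traces + layout) and an optional long-format panel.

    The panel table must reference only wells present in the run. Returns
    the list of files written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}: {exc}") from exc
    paths = [out_dir / "traces.csv", out_dir / "layout.csv"]
    write_plate_kinetics(run, paths[0], paths[1])
    if panel is not None:
        unknown = set(panel["well_id"].astype(str)) - set(run.well_ids)
        if unknown:
            raise ConsistencyError(f"panel references unknown wells: {sorted(unknown)}")
        p = out_dir / "panel.csv"
        panel.to_csv(p, index=False)
        paths.append(p)
    return paths
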