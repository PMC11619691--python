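"""Tidy CSV readers/writers and input validation.

Column units are fixed in the headers (time_s, work_kcal_mol, conc_molar);
no unit inference is performed. Validation reports every violation with
row/column context before any computation runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import FluorescenceTrace
from .synthdata import TraceEnsemble


class ValidationError(Exception):
    """Input file violates the expected schema; message carries context."""


#: schema name -> (required columns, numeric columns)
SCHEMAS = {
    "traces": (["series_id", "roi_id", "time_s", "value"],
               ["time_s", "value"]),
    "work": (["window", "direction", "work_kcal_mol", "temperature_k"],
             ["window", "work_kcal_mol", "temperature_k"]),
    "ct": (["sample", "gene", "ct"], ["ct"]),
    "groups": (["group", "value"], ["value"]),
}


def validate_inputs(path, schema: str) -> pd.DataFrame:
    """Read a CSV and check it against a named schema.

    Checks column presence, numeric types, and (for traces) strictly
    increasing time grids per (series_id, roi_id).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file does not exist")
    if schema not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    required, numeric = SCHEMAS[schema]
    problems = []
    for col in required:
        if col not in df.columns:
            problems.append(f"missing required column '{col}'")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            problems.append(
                f"column '{col}' non-numeric at rows {list(bad[:5])}")
        df[col] = vals
    if schema == "traces":
        for (sid, rid), sub in df.groupby(["series_id", "roi_id"]):
            dt = np.diff(sub["time_s"].to_numpy())
            if np.any(dt <= 0):
                problems.append(
                    f"series '{sid}' roi '{rid}': time_s not strictly "
                    f"increasing")
    if schema == "work":
        bad_dir = ~df["direction"].isin(["forward", "reverse"])
        if bad_dir.any():
            problems.append(
                f"column 'direction' must be forward/reverse; bad rows "
                f"{list(df.index[bad_dir][:5])}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return df


def write_traces_csv(path, ensembles: dict) -> None:
    """Write a dict of series_id -> TraceEnsemble as one tidy CSV."""
    frames = [ens.to_frame(series_id=sid) for sid, ens in ensembles.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path, stimulus_time: float | None = None,
                    ionomycin_time: float | None = None) -> dict:
    """Read a tidy trace CSV back into series_id -> TraceEnsemble.

    An ROI named ``background`` becomes the ensemble's background trace.
    """
    df = validate_inputs(path, "traces")
    out = {}
    for sid, sub in df.groupby("series_id"):
        traces, background = [], None
        for rid, roi in sub.groupby("roi_id"):
            tr = FluorescenceTrace(times=roi["time_s"].to_numpy(),
                                   values=roi["value"].to_numpy(),
                                   roi_id=str(rid),
                                   stimulus_time=stimulus_time,
                                   ionomycin_time=ionomycin_time)
            if rid == "background":
                background = tr
            else:
                traces.append(tr)
        out[sid] = TraceEnsemble(traces=traces, background=background)
    return out


def write_ground_truth(path, truth) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2) + "\n")


def write_report(path, report: dict) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(report, indent=2, default=_default)
                          + "\n")
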