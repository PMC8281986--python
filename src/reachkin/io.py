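"""CSV and JSON dialects used across the pipeline.

Trace CSV: ``time_s,ax_g,ay_g,az_g`` — acceleration in g at 8 decimal places,
which represents every 12-bit ADC code (one LSB = 2⁻⁸ g) exactly.
Events CSV: ``trial,block,condition,P_s,S_s,R_s,A_s,response,correct`` with
empty fields for absent events (omission: empty R/A; anticipation: empty
S/A).  Reports are versioned JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sensor import AccelTrace
from .session import EVENT_COLUMNS

REPORT_SCHEMA_VERSION = 1

TRACE_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g"]


def write_trace(trace: AccelTrace, path) -> None:
    df = pd.DataFrame(
        dict(time_s=trace.time_s, ax_g=trace.acc_g[:, 0],
             ay_g=trace.acc_g[:, 1], az_g=trace.acc_g[:, 2])
    )
    df.to_csv(path, index=False, float_format="%.8f")


def read_trace(path, range_g: float = 8.0, resolution_bits: int = 12) -> AccelTrace:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: trace CSV missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: trace needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 2
        raise ValueError(f"{path}: non-increasing time at line {line}")
    fs = 1.0 / np.median(dt)
    acc = df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    return AccelTrace(t, acc, sample_rate_hz=fs, range_g=range_g,
                      resolution_bits=resolution_bits)


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    for col in ("P_s", "S_s", "R_s", "A_s"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    out["correct"] = out["correct"].map(
        lambda v: "" if v is None or (not isinstance(v, str) and pd.isna(v)) else int(bool(v))
    )
    out.to_csv(path, index=False, columns=EVENT_COLUMNS)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"response": "string"})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: events CSV missing columns {sorted(missing)}")
    return df


def write_report(report: dict, path) -> None:
    payload = dict(schema_version=REPORT_SCHEMA_VERSION, **report)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
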