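"""CSV schemas shared by the generator and the pipeline.

Long (tidy) dialects:

* RR file: ``sub_id, phase_id, test_id, beat_index, rr_ms``
* BP file: ``sub_id, phase_id, test_id, reading_index, sys_mmhg, dia_mmhg``
* symptom file (optional): ``sub_id, test_id, symptom_id``
* ground-truth sidecar: ``sub_id, test_id, delta_sys_true, delta_dia_true``

Schema violations are reported with the offending row number (1-based,
header excluded).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import RRSeries

RR_COLUMNS = ["sub_id", "phase_id", "test_id", "beat_index", "rr_ms"]
BP_COLUMNS = ["sub_id", "phase_id", "test_id", "reading_index",
              "sys_mmhg", "dia_mmhg"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _bad_rows(mask: pd.Series) -> str:
    rows = (np.flatnonzero(mask.to_numpy()) + 1).tolist()
    head = ", ".join(map(str, rows[:10]))
    return head + ("…" if len(rows) > 10 else "")


def write_rr_csv(series_list: list[RRSeries], path) -> None:
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "sub_id": s.sub_id, "phase_id": s.phase_id, "test_id": s.test_id,
            "beat_index": np.arange(1, len(s) + 1), "rr_ms": s.rr}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_rr_csv(path) -> list[RRSeries]:
    df = pd.read_csv(path)
    _require_columns(df, RR_COLUMNS, path)
    bad = ~(np.isfinite(df["rr_ms"]) & (df["rr_ms"] > 0))
    if bad.any():
        raise ValueError(f"{path}: non-positive or missing rr_ms at "
                         f"row(s) {_bad_rows(bad)}")
    out = []
    for (sub, phase, test), grp in df.groupby(
            ["sub_id", "phase_id", "test_id"], sort=True):
        grp = grp.sort_values("beat_index")
        out.append(RRSeries(grp["rr_ms"].to_numpy(dtype=float),
                            int(sub), int(phase), int(test)))
    return out


def write_bp_csv(bp: pd.DataFrame, path) -> None:
    bp[BP_COLUMNS].to_csv(path, index=False)


def read_bp_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, BP_COLUMNS, path)
    for col in ("sys_mmhg", "dia_mmhg"):
        bad = ~(np.isfinite(df[col]) & (df[col] > 40) & (df[col] < 260))
        if bad.any():
            raise ValueError(f"{path}: {col} outside (40, 260) mmHg at "
                             f"row(s) {_bad_rows(bad)}")
    return df


def write_symptom_csv(symptoms: pd.DataFrame, path) -> None:
    symptoms[["sub_id", "test_id", "symptom_id"]].to_csv(path, index=False)


def read_symptom_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["sub_id", "test_id", "symptom_id"], path)
    bad = ~df["symptom_id"].isin([0, 1, 2])
    if bad.any():
        raise ValueError(f"{path}: symptom_id outside 0..2 at row(s) "
                         f"{_bad_rows(bad)}")
    return df


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth[["sub_id", "test_id", "delta_sys_true",
           "delta_dia_true"]].to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["sub_id", "test_id", "delta_sys_true",
                          "delta_dia_true"], path)
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
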