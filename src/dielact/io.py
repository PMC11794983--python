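"""CSV input/output for detection, effort, occasion and curve tables.

All files are plain comma-separated text with a header row and ISO-8601
timestamps; reading is strict (missing columns and unparseable rows are
reported with their location) so silent data corruption cannot propagate
into the models.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["read_detections", "read_effort", "read_occasions",
           "write_detections", "write_effort", "write_occasions",
           "export_curves", "hour_of_day"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_times(df: pd.DataFrame, col: str, path) -> pd.Series:
    parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
    bad = parsed.isna() & df[col].notna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
        raise ValueError(f"{path}: unparseable timestamp(s) in column {col!r} "
                         f"at line(s) {lines}")
    if parsed.isna().any():
        lines = (df.index[parsed.isna()] + 2).tolist()[:5]
        raise ValueError(f"{path}: empty timestamp(s) at line(s) {lines}")
    return parsed


def read_detections(path) -> pd.DataFrame:
    """Read a detection table (columns: site, timestamp [, covariates])."""
    df = pd.read_csv(path)
    _require_columns(df, ["site", "timestamp"], path)
    if len(df) == 0:
        raise ValueError(f"{path}: detection file contains no records")
    df["timestamp"] = _parse_times(df, "timestamp", path)
    df["site"] = df["site"].astype(str)
    return df


def read_effort(path) -> pd.DataFrame:
    """Read an effort table (columns: site, start, end [, covariates])."""
    df = pd.read_csv(path)
    _require_columns(df, ["site", "start", "end"], path)
    if len(df) == 0:
        raise ValueError(f"{path}: effort file contains no deployments")
    df["start"] = _parse_times(df, "start", path)
    df["end"] = _parse_times(df, "end", path)
    df["site"] = df["site"].astype(str)
    if (df["start"] >= df["end"]).any():
        bad = (df.index[df["start"] >= df["end"]] + 2).tolist()[:5]
        raise ValueError(f"{path}: deployment start >= end at line(s) {bad}")
    return df


def read_occasions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["site", "time", "success", "failure"], path)
    df["site"] = df["site"].astype(str)
    return df


def write_detections(det: pd.DataFrame, path) -> None:
    out = det.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_effort(effort: pd.DataFrame, path) -> None:
    out = effort.copy()
    for c in ("start", "end"):
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_occasions(occ: pd.DataFrame, path) -> None:
    occ.to_csv(path, index=False)


def export_curves(curves, path) -> None:
    """Write one or more activity curves to CSV (or JSON by extension).

    Schema: time, estimate, lower, upper, scale[, label] — identical for
    trigonometric, HGAM and KDE curves so they can be overlaid directly.
    """
    if not isinstance(curves, dict):
        curves = {"": curves}
    frames = []
    for label, c in curves.items():
        f = c.to_frame()
        if label:
            f["label"] = label
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(
            {lab or "curve": c.to_frame().to_dict(orient="list")
             for lab, c in curves.items()}, indent=1))
    else:
        out.to_csv(path, index=False)


def hour_of_day(timestamps) -> pd.Series:
    """Fractional hour of day of each timestamp (e.g. 07:15 -> 7.25)."""
    ts = pd.to_datetime(pd.Series(timestamps))
    return (ts - ts.dt.normalize()).dt.total_seconds() / 3600.0
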