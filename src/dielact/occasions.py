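"""Conversion of raw detections + deployment effort into sampling occasions.

The models consume *occasions*: site x time-bin (x day) units with a binary
or binomial detection outcome. ``bin_detections`` produces the binary
site x day x bin indicator ``capt`` (1 if at least one detection fell in the
bin); ``aggregate_binomial`` collapses the day dimension into
(success, failure) counts, optionally split by categorical covariates;
``independent_events`` applies the camera-trap convention of collapsing
same-site records closer than a time threshold into single encounter events
(needed only for the KDE baseline; the hierarchical models bin instead).

Covariates used for aggregation (e.g. Season) are carried on the *effort*
table, one value per deployment interval: failures (days with no detection)
have no detection row to read a covariate from, so covariates must be
attributes of the sampling effort, constant within each deployment interval.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["bin_detections", "aggregate_binomial", "independent_events",
           "normalize_effort"]


def _check_bin_hours(bin_hours: float) -> int:
    n = 24.0 / bin_hours
    if abs(n - round(n)) > 1e-9:
        raise ValueError("24 must be divisible by bin_hours")
    return int(round(n))


def normalize_effort(effort: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping/adjacent deployment intervals per site.

    Intervals carrying covariate columns are merged only when the covariates
    agree; conflicting overlaps raise.
    """
    eff = effort.copy()
    eff["start"] = pd.to_datetime(eff["start"])
    eff["end"] = pd.to_datetime(eff["end"])
    if (eff["start"] >= eff["end"]).any():
        raise ValueError("effort intervals must have start < end")
    covar_cols = [c for c in eff.columns if c not in ("site", "start", "end")]
    out = []
    for (site, *covs), grp in eff.groupby(["site"] + covar_cols, sort=True, dropna=False):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((site, cur_s, cur_e, *covs))
                cur_s, cur_e = s, e
        out.append((site, cur_s, cur_e, *covs))
    res = pd.DataFrame(out, columns=["site", "start", "end"] + covar_cols)
    # detect overlaps across covariate levels (ambiguous effort)
    for site, grp in res.groupby("site"):
        grp = grp.sort_values("start")
        if (grp["start"].iloc[1:].to_numpy() < grp["end"].iloc[:-1].to_numpy()).any():
            raise ValueError(
                f"site {site!r}: overlapping effort intervals with conflicting covariates")
    return res.sort_values(["site", "start"]).reset_index(drop=True)


def bin_detections(det: pd.DataFrame, effort: pd.DataFrame,
                   bin_hours: float = 1.0, effort_mode: str = "full",
                   outside: str = "drop") -> pd.DataFrame:
    """Bin detections into binary site x day x bin occasions.

    Parameters
    ----------
    det : DataFrame with ``site`` and ``timestamp`` columns.
    effort : DataFrame with ``site``, ``start``, ``end`` deployment intervals,
        plus optional covariate columns (constant per interval).
    bin_hours : width of the time-of-day bins; must divide 24.
    effort_mode : ``'full'`` counts a site-day-bin as sampled only when the
        deployment covers the entire bin; ``'any'`` requires any overlap.
    outside : what to do with detections outside all effort intervals:
        ``'drop'`` (with a warning), ``'keep'`` (assign to the calendar
        site-day-bin anyway), or ``'error'``.

    Returns
    -------
    DataFrame with one row per *sampled* site x day x bin:
    columns ``site``, ``date``, ``time`` (bin start hour), ``capt`` (0/1),
    plus any effort covariates.
    """
    n_bins = _check_bin_hours(bin_hours)
    if effort_mode not in ("full", "any"):
        raise ValueError("effort_mode must be 'full' or 'any'")
    if outside not in ("drop", "keep", "error"):
        raise ValueError("outside must be 'drop', 'keep' or 'error'")
    eff = normalize_effort(effort)
    covar_cols = [c for c in eff.columns if c not in ("site", "start", "end")]

    det = det.copy()
    det["timestamp"] = pd.to_datetime(det["timestamp"])
    unknown = set(det["site"]) - set(eff["site"])
    if unknown:
        raise ValueError(f"detections at sites absent from effort table: {sorted(unknown)}")

    # enumerate sampled site-day-bin cells
    frames = []
    bin_starts = np.arange(n_bins) * bin_hours
    for row in eff.itertuples(index=False):
        day0 = row.start.normalize()
        days = pd.date_range(day0, row.end.normalize(), freq="D")
        grid_date = np.repeat(days, n_bins)
        grid_time = np.tile(bin_starts, len(days))
        cell_start = grid_date + pd.to_timedelta(grid_time, unit="h")
        cell_end = cell_start + pd.Timedelta(hours=bin_hours)
        if effort_mode == "full":
            ok = (cell_start >= row.start) & (cell_end <= row.end)
        else:
            ok = (cell_start < row.end) & (cell_end > row.start)
        if not ok.any():
            continue
        f = pd.DataFrame({"site": row.site, "date": grid_date[ok],
                          "time": grid_time[ok]})
        for c in covar_cols:
            f[c] = getattr(row, c)
        frames.append(f)
    if not frames:
        raise ValueError("effort table yields no sampled bins")
    cells = pd.concat(frames, ignore_index=True)
    # a cell may be produced by two intervals in 'any' mode
    cells = cells.drop_duplicates(["site", "date", "time"]).reset_index(drop=True)

    # map detections onto cells
    d = det.copy()
    d["date"] = d["timestamp"].dt.normalize()
    hour = (d["timestamp"] - d["date"]).dt.total_seconds() / 3600.0
    d["time"] = np.floor(hour / bin_hours) * bin_hours

    key = ["site", "date", "time"]
    inside = d.merge(cells[key].assign(_sampled=1), on=key, how="left")
    n_out = int(inside["_sampled"].isna().sum())
    if n_out:
        msg = f"{n_out} detection(s) fall outside all effort intervals"
        if outside == "error":
            raise ValueError(msg)
        if outside == "drop":
            warnings.warn(msg + "; dropping them")
            d = d.loc[inside["_sampled"].notna().to_numpy()]
        else:
            warnings.warn(msg + "; keeping them (their site-day-bin cells are "
                          "added as sampled)")
            extra = d.loc[inside["_sampled"].isna().to_numpy(), key].drop_duplicates()
            cells = pd.concat([cells, extra], ignore_index=True)
            cells = cells.drop_duplicates(key).reset_index(drop=True)

    hit = d[key].drop_duplicates().assign(capt=1)
    occ = cells.merge(hit, on=key, how="left")
    occ["capt"] = occ["capt"].fillna(0).astype(int)
    cols = key + [c for c in occ.columns if c not in key + ["capt"]] + ["capt"]
    return occ[cols].sort_values(key, kind="stable").reset_index(drop=True)


def aggregate_binomial(binary: pd.DataFrame,
                       group_by: list[str] | tuple[str, ...] = ()) -> pd.DataFrame:
    """Collapse binary site x day x bin occasions into binomial counts.

    Returns one row per site x time-bin (x covariate level) with ``success``
    (days with at least one encounter) and ``failure`` (sampled days without).
    Aggregation is done separately for each level of the grouping covariates,
    which must be constant within site x day.
    """
    group_by = list(group_by)
    missing = [c for c in group_by if c not in binary.columns]
    if missing:
        raise ValueError(f"grouping covariates not in table: {missing}")
    for c in group_by:
        nun = binary.groupby(["site", "date"])[c].nunique()
        if (nun > 1).any():
            raise ValueError(
                f"covariate {c!r} varies within a site-day; day-level "
                "aggregation would mix levels — model such covariates on the "
                "binary (per-day) occasions instead")
    keys = ["site", "time"] + group_by
    agg = (binary.groupby(keys, sort=True, dropna=False)["capt"]
           .agg(success="sum", failure=lambda x: int((1 - x).sum()))
           .reset_index())
    agg["success"] = agg["success"].astype(int)
    agg["failure"] = agg["failure"].astype(int)
    return agg


def independent_events(det: pd.DataFrame, threshold_minutes: float,
                       anchor: str = "kept") -> pd.DataFrame:
    """Collapse same-site detections closer than a threshold into events.

    Scans each site's detections chronologically and keeps a record iff at
    least ``threshold_minutes`` elapsed since the last *kept* record
    (``anchor='kept'``, the common convention) or since the immediately
    preceding record (``anchor='seen'``). A threshold of 0 is the identity.
    """
    if threshold_minutes < 0:
        raise ValueError("threshold_minutes must be >= 0")
    if anchor not in ("kept", "seen"):
        raise ValueError("anchor must be 'kept' or 'seen'")
    d = det.copy()
    d["timestamp"] = pd.to_datetime(d["timestamp"])
    if threshold_minutes == 0:
        return d.reset_index(drop=True)
    thr = pd.Timedelta(minutes=threshold_minutes)
    keep_idx = []
    for _, grp in d.groupby("site", sort=False):
        grp = grp.sort_values("timestamp", kind="stable")
        last = None
        prev = None
        for idx, ts in zip(grp.index, grp["timestamp"]):
            ref = prev if anchor == "seen" else last
            if ref is None or ts - ref >= thr:
                keep_idx.append(idx)
                last = ts
            prev = ts
    return d.loc[sorted(keep_idx)].reset_index(drop=True)
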