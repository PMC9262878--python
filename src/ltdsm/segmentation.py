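"""Effort segmentation: tracks and sightings to analysis segments.

The density surface model's sampling unit is the segment: a piece of
on-effort trackline of at most the target length (5 km by default),
carrying its own length, midpoint, group/individual counts and
effectively covered area A_seg = esw x L_seg.  Because the observers
covered a single side of the trackline, the covered area is one-sided:
no doubling anywhere.

Effort tracks are DataFrames of ordered GPS fixes with columns
``transect_id, timestamp, x, y, on_effort`` (x, y projected km);
segments never span an off-effort gap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "declination_to_distance",
    "split_effort",
    "assign_sightings",
    "effective_area",
    "total_effort_km",
]

SEGMENT_COLUMNS = [
    "segment_id",
    "transect_id",
    "mid_x",
    "mid_y",
    "x_start",
    "y_start",
    "x_end",
    "y_end",
    "length_km",
    "t_start",
    "t_end",
    "n_groups",
    "n_individuals",
]


def declination_to_distance(declination_deg, altitude_m: float):
    """Horizontal distance (m) from declination angle below horizontal.

    An observer at altitude h sighting a group at declination angle d
    (degrees below the horizontal) sees it at ground distance
    h / tan(d).  A declination of 90 deg is directly beneath the
    platform; angles at or above the horizon (d <= 0) have no defined
    ground distance.
    """
    dec = np.asarray(declination_deg, dtype=float)
    if altitude_m <= 0:
        raise ValueError("altitude must be positive")
    if np.any(dec <= 0) or np.any(dec > 90):
        raise ValueError("declination must lie in (0, 90] degrees")
    out = altitude_m / np.tan(np.radians(dec))
    return out if out.ndim else float(out)


def _effort_runs(track: pd.DataFrame):
    """Yield contiguous on-effort runs (>= 2 fixes), transect by transect."""
    for _, tr in track.groupby("transect_id", sort=True):
        t = tr.sort_values("timestamp", kind="stable").reset_index(drop=True)
        if t["timestamp"].duplicated().any():
            raise ValueError("timestamps within a transect must be strictly increasing")
        on = t["on_effort"].to_numpy(dtype=bool)
        run_id = np.cumsum(np.concatenate([[0], np.diff(on.astype(int)) != 0]))
        for rid in np.unique(run_id):
            mask = run_id == rid
            if on[mask][0] and mask.sum() >= 2:
                yield t[mask].reset_index(drop=True)


def split_effort(
    track: pd.DataFrame, target_km: float = 5.0, min_km: float = 1.0
) -> pd.DataFrame:
    """Cut each contiguous on-effort run into consecutive segments.

    Pieces are exactly ``target_km`` long except a terminal remainder;
    remainders shorter than ``min_km`` are discarded.  Lengths are sums
    of projected chord lengths between fixes; midpoints and boundary
    times are interpolated along the track.  Returns a segment table
    (one row per segment) with zeroed count columns.
    """
    segments = []
    for run in _effort_runs(track):
        x = run["x"].to_numpy(dtype=float)
        y = run["y"].to_numpy(dtype=float)
        ts = run["timestamp"].to_numpy()
        step = np.hypot(np.diff(x), np.diff(y))
        cum = np.concatenate([[0.0], np.cumsum(step)])
        total = cum[-1]
        if total < min_km:
            continue
        cuts = np.arange(0.0, total, target_km)
        cuts = np.append(cuts, total)
        t_num = ts.astype("datetime64[ns]").astype("int64").astype(float)
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b - a < min_km:
                continue  # discarded terminal remainder
            mid = 0.5 * (a + b)
            seg = {
                "transect_id": run["transect_id"].iloc[0],
                "mid_x": float(np.interp(mid, cum, x)),
                "mid_y": float(np.interp(mid, cum, y)),
                "x_start": float(np.interp(a, cum, x)),
                "y_start": float(np.interp(a, cum, y)),
                "x_end": float(np.interp(b, cum, x)),
                "y_end": float(np.interp(b, cum, y)),
                "length_km": float(b - a),
                "t_start": pd.Timestamp(int(np.interp(a, cum, t_num))),
                "t_end": pd.Timestamp(int(np.interp(b, cum, t_num))),
                "n_groups": 0,
                "n_individuals": 0,
            }
            segments.append(seg)
    out = pd.DataFrame(segments, columns=[c for c in SEGMENT_COLUMNS if c != "segment_id"])
    out.insert(0, "segment_id", [f"seg{i:05d}" for i in range(len(out))])
    return out


def total_effort_km(track: pd.DataFrame) -> float:
    """Total on-effort track length in km (sum over contiguous runs)."""
    total = 0.0
    for run in _effort_runs(track):
        total += float(
            np.hypot(np.diff(run["x"].to_numpy(float)), np.diff(run["y"].to_numpy(float))).sum()
        )
    return total


def assign_sightings(
    segments: pd.DataFrame, sightings: pd.DataFrame, truncation_w: float
) -> pd.DataFrame:
    """Attribute each usable sighting to exactly one segment.

    A sighting counts if its perpendicular distance is within the
    truncation distance.  Assignment is by recording time: the segment
    of the same transect whose [t_start, t_end] interval contains the
    timestamp.  Sightings inside a transect's effort span but at a
    segment boundary fall to the nearest midpoint; sightings outside
    all effort spans are excluded with a warning.  Returns a copy of
    the segment table with updated counts.
    """
    seg = segments.copy()
    n_groups = seg["n_groups"].to_numpy().copy()
    n_ind = seg["n_individuals"].to_numpy().copy()
    dropped = 0
    for _, s in sightings.iterrows():
        if s["perp_distance"] > truncation_w:
            continue
        cand = seg.index[seg["transect_id"] == s["transect_id"]]
        if len(cand) == 0:
            dropped += 1
            continue
        ts = pd.Timestamp(s["timestamp"])
        inside = [
            i
            for i in cand
            if seg.loc[i, "t_start"] <= ts <= seg.loc[i, "t_end"]
        ]
        if inside:
            i = inside[0]
        else:
            t0 = seg.loc[cand, "t_start"].min()
            t1 = seg.loc[cand, "t_end"].max()
            if not (t0 <= ts <= t1):
                dropped += 1
                continue
            if "x" in s.index and np.isfinite(s.get("x", np.nan)):
                d2 = (seg.loc[cand, "mid_x"] - s["x"]) ** 2 + (
                    seg.loc[cand, "mid_y"] - s["y"]
                ) ** 2
                i = d2.idxmin()
            else:
                gap = np.minimum(
                    abs((seg.loc[cand, "t_start"] - ts).dt.total_seconds()),
                    abs((seg.loc[cand, "t_end"] - ts).dt.total_seconds()),
                )
                i = gap.idxmin()
        pos = seg.index.get_loc(i)
        n_groups[pos] += 1
        n_ind[pos] += int(s["group_size"])
    if dropped:
        warnings.warn(f"{dropped} sighting(s) outside all effort spans were excluded")
    seg["n_groups"] = n_groups
    seg["n_individuals"] = n_ind
    return seg


def effective_area(length_km, esw_km: float):
    """One-sided effectively covered area A_seg = esw x L_seg (km^2)."""
    if not esw_km > 0:
        raise ValueError("esw must be positive")
    L = np.asarray(length_km, dtype=float)
    out = esw_km * L
    return out if out.ndim else float(out)
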