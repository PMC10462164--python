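"""Cell-migration and 3D-invasion track statistics.

Consumes long-format track tables (``track_id, frame, t, x, y`` and
optionally ``condition``) exported from tracking software, applies the
assay-specific track filters, and computes per-track motility metrics:

- accumulated distance: total path length (sum of step lengths),
- net, lateral (x) and vertical (y) displacement: last minus first position,
- straightness: net displacement / accumulated distance, in [0, 1],
- speed: accumulated distance / elapsed time,
- parallel FMI (forward motion index): vertical displacement / accumulated
  distance — the signed fraction of movement directed along the
  chemoattractant gradient (+y by convention).

Stationary tracks (zero accumulated distance) get straightness = FMI = 0 so
cohort summaries stay computable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "accumulated_distance",
    "track_metrics",
    "filter_tracks_2d",
    "filter_tracks_3d",
    "proximity_exclusion",
    "group_summary",
]

_TRACK_COLS = ("track_id", "frame", "t", "x", "y")


def _validate(tracks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _TRACK_COLS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing columns {missing}")
    return tracks.sort_values(["track_id", "frame"])


def accumulated_distance(xy: np.ndarray) -> float:
    """Total path length: sum of Euclidean distances between consecutive samples."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        raise ValueError("need at least 2 samples")
    return float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))


def track_metrics(
    tracks: pd.DataFrame,
    gradient_axis: str = "y",
    signed_fmi: bool = True,
    speed_mode: str = "accumulated",
) -> pd.DataFrame:
    """Per-track motility metrics.

    ``gradient_axis`` selects which coordinate counts as gradient-parallel
    ("vertical"); the FMI is signed toward the gradient unless
    ``signed_fmi=False``.  ``speed_mode`` is ``"accumulated"`` (path length
    over elapsed time, default) or ``"per_step"`` (mean instantaneous step
    speed).  Tracks with fewer than 2 samples are dropped as unmeasurable.
    """
    if gradient_axis not in ("x", "y"):
        raise ValueError("gradient_axis must be 'x' or 'y'")
    if speed_mode not in ("accumulated", "per_step"):
        raise ValueError("speed_mode must be 'accumulated' or 'per_step'")
    tracks = _validate(tracks)
    lateral_axis = "x" if gradient_axis == "y" else "y"

    rows = []
    for tid, g in tracks.groupby("track_id", sort=True):
        if len(g) < 2:
            continue
        xy = g[["x", "y"]].to_numpy(float)
        tt = g["t"].to_numpy(float)
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        acc = float(steps.sum())
        net_vec = xy[-1] - xy[0]
        net = float(np.linalg.norm(net_vec))
        vertical = float(net_vec[1] if gradient_axis == "y" else net_vec[0])
        lateral = float(net_vec[0] if gradient_axis == "y" else net_vec[1])
        elapsed = float(tt[-1] - tt[0])
        if speed_mode == "accumulated":
            speed = acc / elapsed if elapsed > 0 else float("nan")
        else:
            dts = np.diff(tt)
            speed = float(np.mean(steps / dts)) if np.all(dts > 0) else float("nan")
        straight = net / acc if acc > 0 else 0.0
        fmi = vertical / acc if acc > 0 else 0.0
        if not signed_fmi:
            fmi = abs(fmi)
        row = {
            "track_id": tid,
            "n_timepoints": len(g),
            "first_frame": int(g["frame"].iloc[0]),
            "accumulated_distance": acc,
            "net_displacement": net,
            "lateral_displacement": lateral,
            "vertical_displacement": vertical,
            "straightness": straight,
            "speed": speed,
            "parallel_fmi": fmi,
        }
        if "condition" in g.columns:
            row["condition"] = g["condition"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def filter_tracks_3d(tracks: pd.DataFrame) -> pd.DataFrame:
    """3D invasion filter: discard tracks shorter than 3 timepoints."""
    tracks = _validate(tracks)
    counts = tracks.groupby("track_id")["frame"].transform("size")
    return tracks.loc[counts >= 3]


def filter_tracks_2d(tracks: pd.DataFrame) -> pd.DataFrame:
    """2D migration filter: keep tracks with >= 5 timepoints starting before frame 5."""
    tracks = _validate(tracks)
    g = tracks.groupby("track_id")["frame"]
    counts = g.transform("size")
    first = g.transform("min")
    return tracks.loc[(counts >= 5) & (first < 5)]


def proximity_exclusion(
    positions: np.ndarray,
    ids: np.ndarray | None = None,
    radius_um: float = 35.0,
) -> np.ndarray:
    """Cells eligible for tracking: no neighbour strictly closer than ``radius_um``.

    Crowded cells collide and confound single-cell motility, so any cell
    with at least one neighbour at distance < radius (default 35 µm) is
    excluded.  Returns the ids (indices when ``ids`` is None) of eligible
    cells.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    ids = np.arange(n) if ids is None else np.asarray(ids)
    if n <= 1:
        return ids
    tree = cKDTree(positions)
    crowded = np.zeros(n, dtype=bool)
    for i, j in tree.query_pairs(r=radius_um):
        if np.linalg.norm(positions[i] - positions[j]) < radius_um:  # strict
            crowded[i] = crowded[j] = True
    return ids[~crowded]


def group_summary(metrics: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """Per-condition mean and sample SD (n−1) of every track metric.

    Conditions with a single track get NaN SDs; empty conditions simply do
    not appear (the caller sees the n column).
    """
    if by not in metrics.columns:
        raise ValueError(f"metrics table has no '{by}' column")
    value_cols = [
        c
        for c in metrics.columns
        if c not in (by, "track_id") and pd.api.types.is_numeric_dtype(metrics[c])
    ]
    out = metrics.groupby(by)[value_cols].agg(["mean", lambda s: s.std(ddof=1)])
    out.columns = [f"{c}_{'sd' if fn == '<lambda_0>' else fn}" for c, fn in out.columns]
    out.insert(0, "n_tracks", metrics.groupby(by).size())
    return out.reset_index()
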