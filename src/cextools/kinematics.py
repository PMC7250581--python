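"""Convergence/extension kinematics from track tables.

All analyses run on (x, y) analysis coordinates in micrometres, with the
dorsal midline registered to x = 0 (+x mediolateral-right, +y anterior).
Displacement is net (first to last frame); path length appears only inside
mean speed. ML and AP readouts are computed independently, mirroring how
track displacement is plotted against starting position per axis: a
negative ML slope reads out convergence, a positive AP slope extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import TestResult


@dataclass(frozen=True)
class GradientFit:
    """OLS fit of axis displacement against axis starting position."""

    slope: float
    intercept: float
    r_squared: float
    stderr: float
    n: int


def compute_track_displacements(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-track net displacements and mean speed.

    Returns one row per track: starting position (x0, y0), net displacement
    per axis (dx, dy), their absolute values, and mean speed = path length /
    elapsed time. Single-frame tracks are skipped with a warning.
    """
    required = {"track_id", "frame", "time_min", "x_um", "y_um"}
    missing = required - set(tracks.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    rows = []
    skipped = 0
    for tid, grp in tracks.sort_values("frame").groupby("track_id"):
        if len(grp) < 2:
            skipped += 1
            continue
        x = grp.x_um.to_numpy()
        y = grp.y_um.to_numpy()
        t = grp.time_min.to_numpy()
        steps = np.hypot(np.diff(x), np.diff(y))
        elapsed = t[-1] - t[0]
        rows.append(
            {
                "track_id": tid,
                "x0_um": x[0],
                "y0_um": y[0],
                "dx_um": x[-1] - x[0],
                "dy_um": y[-1] - y[0],
                "abs_dx_um": abs(x[-1] - x[0]),
                "abs_dy_um": abs(y[-1] - y[0]),
                "mean_speed_um_per_min": steps.sum() / elapsed if elapsed > 0 else np.nan,
                "n_frames": len(grp),
            }
        )
    if skipped:
        warnings.warn(f"skipped {skipped} single-frame track(s)", stacklevel=2)
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "x0_um",
            "y0_um",
            "dx_um",
            "dy_um",
            "abs_dx_um",
            "abs_dy_um",
            "mean_speed_um_per_min",
            "n_frames",
        ],
    )


def fit_displacement_gradient(displacements: pd.DataFrame, axis: str = "ML") -> GradientFit:
    """OLS of per-track axis displacement against axis starting position.

    axis "ML" regresses dx on x0; "AP" regresses dy on y0. The sign of the
    slope is the convergence (negative) / extension (positive) readout.
    """
    if axis == "ML":
        x, d = displacements.x0_um.to_numpy(), displacements.dx_um.to_numpy()
    elif axis == "AP":
        x, d = displacements.y0_um.to_numpy(), displacements.dy_um.to_numpy()
    else:
        raise ValueError(f"axis must be 'ML' or 'AP', got {axis!r}")
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 tracks with distinct starting positions")
    res = sps.linregress(x, d)
    return GradientFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr=float(res.stderr),
        n=len(x),
    )


def count_midline_crossings(tracks: pd.DataFrame, midline_x: float = 0.0):
    """Count sign changes of (x - midline) along each track.

    A crossing is a sign change between consecutive frames; frames exactly
    on the midline inherit the preceding sign (a touch-and-return is not a
    crossing). Returns (total_crossings, per_track DataFrame with counts
    and a crossed flag).
    """
    rows = []
    for tid, grp in tracks.sort_values("frame").groupby("track_id"):
        s = np.sign(grp.x_um.to_numpy() - midline_x)
        # zeros attach to the preceding sign; leading zeros to the first
        # nonzero sign that follows
        nz = np.flatnonzero(s)
        if len(nz) == 0:
            count = 0
        else:
            s = s.copy()
            s[: nz[0]] = s[nz[0]]
            for i in range(1, len(s)):
                if s[i] == 0:
                    s[i] = s[i - 1]
            count = int(np.sum(s[1:] != s[:-1]))
        rows.append({"track_id": tid, "n_crossings": count, "crossed": count > 0})
    per_track = pd.DataFrame(rows, columns=["track_id", "n_crossings", "crossed"])
    return int(per_track.n_crossings.sum()), per_track


def summarize_division_positions(events, center, axis_direction) -> dict:
    """Axial/lateral offsets of division events and a uniformity test.

    ``events`` holds (x, y) positions (a time column, if present in a
    DataFrame, is ignored); offsets are signed projections of
    (event - center) onto the unit ``axis_direction`` and its left normal.
    The axial sample is compared to a uniform law on its observed span by a
    one-sample Kolmogorov-Smirnov test (skipped when the span is zero).
    """
    if isinstance(events, pd.DataFrame):
        pts = events[["x_um", "y_um"]].to_numpy(dtype=float)
    else:
        pts = np.atleast_2d(np.asarray(events, dtype=float))[:, -2:]
    if len(pts) == 0:
        raise ValueError("no division events supplied")
    u = np.asarray(axis_direction, dtype=float)
    if not np.isclose(np.linalg.norm(u), 1.0, atol=1e-6):
        raise ValueError("axis_direction must be a unit vector")
    c = np.asarray(center, dtype=float)
    rel = pts - c
    axial = rel @ u
    lateral = rel @ np.array([-u[1], u[0]])
    lo, hi = axial.min(), axial.max()
    if hi > lo:
        ks = sps.kstest(axial, "uniform", args=(lo, hi - lo))
        uniformity = TestResult(
            float(ks.statistic), float(ks.pvalue), None, (len(axial),), "ks_uniform"
        )
    else:
        uniformity = None
    return {
        "axial_um": axial,
        "lateral_um": lateral,
        "axial_sd_um": float(axial.std(ddof=1)) if len(axial) > 1 else 0.0,
        "lateral_sd_um": float(lateral.std(ddof=1)) if len(lateral) > 1 else 0.0,
        "uniformity": uniformity,
    }


def summarize_kinematics(tracks: pd.DataFrame, midline_x: float = 0.0) -> dict:
    """Per-dataset kinematics bundle: displacement table, ML/AP gradient
    fits, and midline-crossing count."""
    disp = compute_track_displacements(tracks)
    ml = fit_displacement_gradient(disp, "ML")
    ap = fit_displacement_gradient(disp, "AP")
    n_cross, per_track = count_midline_crossings(tracks, midline_x)
    return {
        "displacements": disp,
        "ml_gradient": ml,
        "ap_gradient": ap,
        "n_midline_crossings": n_cross,
        "crossings_per_track": per_track,
    }
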