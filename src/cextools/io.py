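"""Readers and writers for the pipeline's plain-text and TIFF formats.

Tables are UTF-8 CSV with a mandatory header row and '.' decimal
separator; frame indices are 0-based; coordinates are micrometres in the
analysis frame (+x ML-right, +y anterior). Image stacks are plain
multi-page TIFF (z-major page order, 16-bit unsigned) with a JSON sidecar
carrying ``{"voxel_size_um": [z, y, x]}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphometry import ExplantShape
from .polarity import CellOutline
from .tracking import MetadataError

SCHEMA_VERSION = 1

TRACK_COLUMNS = ["track_id", "frame", "time_min", "x_um", "y_um"]
CELL_COLUMNS = ["cell_id", "frame", "vertex_idx", "x_um", "y_um"]


# ---------------------------------------------------------------------------
# tables


def write_tracks(path, tracks: pd.DataFrame) -> None:
    cols = TRACK_COLUMNS + (["z_um"] if "z_um" in tracks.columns else [])
    tracks[cols].to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing track columns {sorted(missing)}")
    return df


def write_cells(path, outlines: list[CellOutline]) -> None:
    rows = []
    for o in outlines:
        for k, (x, y) in enumerate(o.vertices):
            rows.append((o.cell_id, o.frame, k, x, y))
    pd.DataFrame(rows, columns=CELL_COLUMNS).to_csv(path, index=False)


def read_cells(path) -> list[CellOutline]:
    df = pd.read_csv(path)
    missing = set(CELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cell columns {sorted(missing)}")
    outlines = []
    for (cid, frame), grp in df.groupby(["cell_id", "frame"], sort=True):
        grp = grp.sort_values("vertex_idx")
        outlines.append(
            CellOutline(
                cell_id=int(cid),
                frame=int(frame),
                vertices=grp[["x_um", "y_um"]].to_numpy(dtype=float),
            )
        )
    return outlines


def write_protrusions(path, angles_deg, cell_ids=None) -> None:
    angles = np.asarray(angles_deg, dtype=float).ravel()
    ids = np.arange(len(angles)) if cell_ids is None else np.asarray(cell_ids)
    pd.DataFrame({"cell_id": ids, "angle_deg": angles}).to_csv(path, index=False)


def read_protrusions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "angle_deg" not in df.columns:
        raise ValueError(f"{path}: missing 'angle_deg' column")
    return df


def write_puncta(path, puncta_by_cell: dict) -> None:
    rows = [
        (cid, x, y)
        for cid, pts in sorted(puncta_by_cell.items())
        for x, y in np.atleast_2d(pts)
    ]
    pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um"]).to_csv(path, index=False)


def read_puncta(path) -> dict:
    df = pd.read_csv(path)
    return {
        int(cid): grp[["x_um", "y_um"]].to_numpy(dtype=float)
        for cid, grp in df.groupby("cell_id")
    }


def write_landmarks(path, landmarks: dict) -> None:
    rows = [(name, xy[0], xy[1]) for name, xy in sorted(landmarks.items())]
    pd.DataFrame(rows, columns=["name", "x_um", "y_um"]).to_csv(path, index=False)


def read_landmarks(path) -> dict:
    df = pd.read_csv(path)
    return {r["name"]: (float(r.x_um), float(r.y_um)) for _, r in df.iterrows()}


# ---------------------------------------------------------------------------
# shapes and JSON


def write_shape(path, shape: ExplantShape) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "boundary_um": np.asarray(shape.boundary).tolist(),
        "midline_um": np.asarray(shape.midline).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_shape(path) -> ExplantShape:
    payload = json.loads(Path(path).read_text())
    return ExplantShape(
        boundary=np.asarray(payload["boundary_um"], dtype=float),
        midline=np.asarray(payload["midline_um"], dtype=float),
    )


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# image stacks


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_stack(path, stack: np.ndarray, voxel_size_um) -> None:
    """Write a stack as 16-bit multi-page TIFF with a voxel-size sidecar."""
    arr = np.clip(np.round(np.asarray(stack)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr, photometric="minisblack")
    voxel = [float(v) for v in np.atleast_1d(voxel_size_um)]
    _sidecar(path).write_text(json.dumps({"voxel_size_um": voxel}))


def read_stack(path):
    """Read a TIFF stack and its sidecar; returns (float array, voxel_size)."""
    arr = tifffile.imread(path).astype(float)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise MetadataError(f"missing voxel-size sidecar {sidecar}")
    voxel = json.loads(sidecar.read_text())["voxel_size_um"]
    return arr, tuple(float(v) for v in voxel)


# ---------------------------------------------------------------------------
# coordinate converters


def pixel_to_analysis(rows, cols, pixel_size_um, origin_xy=(0.0, 0.0), y_up: bool = False):
    """Convert image (row, col) indices to analysis (x, y) in micrometres.

    With ``y_up`` (anterior-up images), rows increase downward so y runs
    opposite to the row index; origin_xy is the analysis position of pixel
    (0, 0).
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    x = origin_xy[0] + cols * pixel_size_um
    sign = -1.0 if y_up else 1.0
    y = origin_xy[1] + sign * rows * pixel_size_um
    return x, y


def analysis_to_pixel(x_um, y_um, pixel_size_um, origin_xy=(0.0, 0.0), y_up: bool = False):
    """Inverse of :func:`pixel_to_analysis` (returns fractional row, col)."""
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    cols = (x - origin_xy[0]) / pixel_size_um
    sign = -1.0 if y_up else 1.0
    rows = sign * (y - origin_xy[1]) / pixel_size_um
    return rows, cols
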