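"""Explant and neural-plate morphometrics from annotation geometry.

Explant length is the arc length of a hand-drawn midline polyline (so
curvature is accounted for); width is measured along the perpendicular to
the midline at its arc-length midpoint, between the two boundary
intersections. Neural-plate width/length are straight-line distances
between named landmark points. Midlines and landmarks are annotation
inputs — no automatic skeletonization is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point, Polygon

from .polarity import GeometryError


@dataclass
class ExplantShape:
    """Explant silhouette: simple boundary polygon plus midline polyline,
    both in micrometres."""

    boundary: np.ndarray  # (n, 2)
    midline: np.ndarray   # (m, 2)

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        self.midline = np.asarray(self.midline, dtype=float)
        if len(self.boundary) < 3:
            raise GeometryError("boundary needs at least 3 vertices")
        if len(self.midline) < 2:
            raise GeometryError("midline needs at least 2 vertices")
        if not Polygon(self.boundary).is_valid:
            raise GeometryError("boundary polygon is not simple")


@dataclass(frozen=True)
class MorphometryResult:
    length_um: float
    width_um: float
    ratio: float
    midpoint_offset: float  # fraction of arc length the width line was moved


class LandmarkError(KeyError):
    """A required named landmark is missing."""


def _arc_lengths(polyline: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def _point_at(polyline: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    s = np.clip(s, 0.0, cum[-1])
    x = np.interp(s, cum, polyline[:, 0])
    y = np.interp(s, cum, polyline[:, 1])
    return np.array([x, y])


def _width_at(shape: ExplantShape, cum: np.ndarray, s: float) -> float:
    pt = _point_at(shape.midline, cum, s)
    ds = max(cum[-1] * 1e-3, 1e-9)
    ahead = _point_at(shape.midline, cum, s + ds)
    behind = _point_at(shape.midline, cum, s - ds)
    tangent = ahead - behind
    tnorm = np.linalg.norm(tangent)
    if tnorm == 0:
        raise GeometryError("midline tangent undefined at the midpoint")
    normal = np.array([-tangent[1], tangent[0]]) / tnorm
    span = shape.boundary.max(axis=0) - shape.boundary.min(axis=0)
    reach = 2.0 * np.linalg.norm(span) + 1.0
    line = LineString([pt - reach * normal, pt + reach * normal])
    inter = line.intersection(Polygon(shape.boundary).exterior)
    if isinstance(inter, Point):
        pts = [inter]
    elif isinstance(inter, MultiPoint):
        pts = list(inter.geoms)
    else:
        pts = [g for g in getattr(inter, "geoms", []) if isinstance(g, Point)]
    if len(pts) != 2:
        raise GeometryError(
            f"width line at arc position {s:.3g} crossed the boundary "
            f"{len(pts)} times (expected 2)"
        )
    return float(pts[0].distance(pts[1]))


def measure_length_width(shape: ExplantShape) -> MorphometryResult:
    """Midline length, perpendicular width near the midpoint, and their
    ratio.

    If the perpendicular at the exact arc-length midpoint fails to cross the
    boundary exactly twice (possible for concave silhouettes), it is retried
    at +/-5% of the arc length and the offset used is reported.
    """
    cum = _arc_lengths(shape.midline)
    length = float(cum[-1])
    if length <= 0:
        raise GeometryError("midline has zero length")
    last_err: GeometryError | None = None
    for offset in (0.0, 0.05, -0.05):
        try:
            width = _width_at(shape, cum, length * (0.5 + offset))
        except GeometryError as err:
            last_err = err
            continue
        return MorphometryResult(length, width, length / width, offset)
    raise GeometryError(
        f"could not measure width near the midline midpoint: {last_err}"
    )


_WIDTH_KEYS = ("left_border", "right_border")
_LENGTH_KEYS = ("anterior_tip", "posterior_tip")


def measure_neural_plate(landmarks: dict) -> tuple[float, float]:
    """Neural-plate width and length from named landmark points.

    Width is the distance between the left and right borders of the dlx3b
    expression domain (at the hindbrain level); length is anterior tip to
    posterior tip. Raises :class:`LandmarkError` naming the first missing
    landmark.
    """
    for key in _WIDTH_KEYS + _LENGTH_KEYS:
        if key not in landmarks:
            raise LandmarkError(f"missing landmark {key!r}")
    pts = {k: np.asarray(landmarks[k], dtype=float) for k in landmarks}
    width = float(np.linalg.norm(pts["left_border"] - pts["right_border"]))
    length = float(np.linalg.norm(pts["anterior_tip"] - pts["posterior_tip"]))
    return width, length
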