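"""Planar cell polarity readouts: elongation, mediolateral alignment,
protrusion orientation, and Prickle-GFP membrane-punctum localization.

Coordinate convention (package-wide): +x is the mediolateral (ML) axis
pointing right, +y is anterior (AP axis); angles are measured
counterclockwise from +x in degrees. Cell axes are undirected, so
orientations live on [0, 180) and alignment angles (acute angle to the ML
axis) on [0, 90]; 0 deg means perfectly ML-aligned.

Ellipse fitting uses exact polygon second moments (Green's theorem), not
rasterized masks, so results are independent of image resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .stats import TestResult, chi_square, ks_two_sample

#: aspect-ratio margin below which a cell's orientation is unreliable
ORIENTATION_EPS = 0.05


class GeometryError(ValueError):
    """Raised for degenerate input geometry."""


@dataclass
class CellOutline:
    """Polygonal cell silhouette in analysis coordinates (micrometres)."""

    cell_id: int
    vertices: np.ndarray  # (n, 2) float, ordered ring without repeated close
    frame: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError("vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise GeometryError("a polygon needs at least 3 vertices")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a polygon."""

    theta_deg: float      # major-axis orientation in [0, 180)
    aspect_ratio: float   # major/minor axis length, >= 1
    centroid: tuple[float, float]
    area: float


def _polygon_moments(verts: np.ndarray):
    """Area, centroid and per-unit-area central second moments of a simple
    polygon, by the exact shoelace formulas. Works for either vertex
    orientation (signs cancel in the ratios)."""
    x = verts[:, 0]
    y = verts[:, 1]
    x1 = np.roll(x, -1)
    y1 = np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-12:
        raise GeometryError("polygon has (near-)zero area")
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    # second moments about the origin, divided by signed area
    ixx = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    iyy = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    mu20 = iyy / a - cx * cx   # variance along x
    mu02 = ixx / a - cy * cy   # variance along y
    mu11 = ixy / a - cx * cy
    return abs(a), (cx, cy), mu20, mu02, mu11


def fit_ellipse(outline: CellOutline) -> EllipseFit:
    """Fit the moment-equivalent ellipse of a cell outline.

    The major-axis orientation is theta = 1/2 * atan2(2*mu11, mu20 - mu02)
    mapped into [0, 180); the aspect ratio is sqrt(lmax/lmin) of the
    second-moment matrix eigenvalues.
    """
    area, centroid, mu20, mu02, mu11 = _polygon_moments(outline.vertices)
    theta = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
    theta %= 180.0
    common = 0.5 * (mu20 + mu02)
    delta = np.sqrt(0.25 * (mu20 - mu02) ** 2 + mu11**2)
    lmax, lmin = common + delta, common - delta
    if lmin <= 0:
        raise GeometryError("degenerate polygon: zero minor-axis moment")
    return EllipseFit(float(theta), float(np.sqrt(lmax / lmin)), centroid, area)


def alignment_angle(theta_deg: float) -> float:
    """Fold an orientation into the acute angle to the ML axis, [0, 90]."""
    t = float(theta_deg) % 180.0
    return min(t, 180.0 - t)


def measure_cells(outlines, eps: float = ORIENTATION_EPS) -> pd.DataFrame:
    """Per-cell polarity table: orientation, alignment, aspect ratio.

    Cells rounder than ``aspect_ratio < 1 + eps`` get
    ``reliable_orientation=False`` (their major axis is ill-defined) and are
    excluded from alignment summaries downstream.
    """
    rows = []
    for o in outlines:
        fit = fit_ellipse(o)
        rows.append(
            {
                "cell_id": o.cell_id,
                "frame": o.frame,
                "theta_deg": fit.theta_deg,
                "alignment_deg": alignment_angle(fit.theta_deg),
                "aspect_ratio": fit.aspect_ratio,
                "reliable_orientation": fit.aspect_ratio >= 1.0 + eps,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "frame",
            "theta_deg",
            "alignment_deg",
            "aspect_ratio",
            "reliable_orientation",
        ],
    )


def summarize_alignment(alpha_deg) -> dict:
    """Median alignment angle, fraction within 20 deg of ML, and the sorted
    sample (ECDF support) for downstream K-S comparisons."""
    a = np.asarray(alpha_deg, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("no alignment angles supplied")
    srt = np.sort(a)
    return {
        "n": int(a.size),
        "median_deg": float(np.median(a)),
        "fraction_le_20deg": float(np.mean(a <= 20.0)),
        "sorted_angles": srt,
    }


def compare_alignment(alpha_a, alpha_b) -> TestResult:
    """K-S comparison of two alignment-angle samples."""
    return ks_two_sample(alpha_a, alpha_b)


def classify_protrusion(
    phi_deg: float, scheme: str = "quadrant", half_width: float | None = None
) -> str:
    """Categorize a protrusion angle as ML, AP or neither.

    quadrant (default, half_width 45): ML when the angular distance to the ML
    axis {0, 180} is < 45 deg, AP otherwise (the 45-deg boundary counts as
    AP). sector (half_width 30): ML within 30 deg of the ML axis, AP within
    30 deg of the AP axis {90, 270}, neither for the remaining 120 deg.
    """
    phi = float(phi_deg) % 360.0
    d_ml = min(abs(((phi - c) + 180.0) % 360.0 - 180.0) for c in (0.0, 180.0))
    d_ap = min(abs(((phi - c) + 180.0) % 360.0 - 180.0) for c in (90.0, 270.0))
    if scheme == "quadrant":
        hw = 45.0 if half_width is None else float(half_width)
        return "ML" if d_ml < hw else "AP"
    if scheme == "sector":
        hw = 30.0 if half_width is None else float(half_width)
        if d_ml < hw:
            return "ML"
        if d_ap < hw:
            return "AP"
        return "neither"
    raise ValueError(f"unknown protrusion scheme {scheme!r}")


def classify_protrusions(
    phi_deg, scheme: str = "quadrant", half_width: float | None = None
) -> pd.DataFrame:
    phis = np.asarray(phi_deg, dtype=float).ravel()
    return pd.DataFrame(
        {
            "angle_deg": phis,
            "category": [classify_protrusion(p, scheme, half_width) for p in phis],
        }
    )


def protrusion_histogram(phi_deg, bin_width: float = 20.0) -> np.ndarray:
    """Circular histogram counts over half-open bins [0, w), [w, 2w), ...

    360 must be divisible by the bin width (the paper-style rose diagram uses
    20-deg bins, 18 in total).
    """
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide 360")
    nb = int(round(360.0 / bin_width))
    phis = np.asarray(phi_deg, dtype=float).ravel() % 360.0
    idx = np.floor(phis / bin_width).astype(int)
    idx[idx == nb] = 0  # guard float edge at exactly 360
    counts = np.bincount(idx, minlength=nb)
    return counts


def compare_protrusion_distributions(counts_a, counts_b) -> TestResult:
    """Chi-square comparison of protrusion category counts between two
    conditions (2 x k contingency table, df = k - 1)."""
    return chi_square(np.vstack([counts_a, counts_b]))


@dataclass
class PkRecord:
    """Prickle-GFP localization call for one cell."""

    cell_id: int
    category: str  # anterior | membrane_other | none
    n_puncta: int = 0
    n_membrane: int = 0


def score_pk_localization(
    outline: CellOutline,
    puncta,
    anterior_dir=(0.0, 1.0),
    membrane_dist: float = 1.0,
    sector_half: float = 45.0,
) -> PkRecord:
    """Score a cell's Pk-GFP puncta as anterior / membrane_other / none.

    A punctum is membrane-associated when its distance to the polygon
    boundary is at most ``membrane_dist`` (micrometres). Its bearing is the
    signed angle between (punctum - centroid) and ``anterior_dir``; the cell
    is called "anterior" if any membrane punctum lies within ``sector_half``
    degrees of anterior, else "membrane_other" if it has any membrane
    punctum, else "none".
    """
    a = np.asarray(anterior_dir, dtype=float)
    norm = np.linalg.norm(a)
    if not np.isclose(norm, 1.0, atol=1e-6):
        raise ValueError("anterior_dir must be a unit vector")
    poly = outline.polygon()
    fit = fit_ellipse(outline)
    cx, cy = fit.centroid
    boundary = poly.exterior
    n_membrane = 0
    any_anterior = False
    pts = np.atleast_2d(np.asarray(puncta, dtype=float)) if len(puncta) else np.empty((0, 2))
    for px, py in pts:
        pt = Point(px, py)
        if poly.distance(pt) > membrane_dist:
            warnings.warn(
                f"punctum ({px:.2f}, {py:.2f}) lies outside cell {outline.cell_id} "
                f"beyond the membrane distance; ignored",
                stacklevel=2,
            )
            continue
        if boundary.distance(pt) > membrane_dist:
            continue  # interior punctum, not membrane-associated
        n_membrane += 1
        v = np.array([px - cx, py - cy])
        if np.linalg.norm(v) == 0:
            continue
        bearing = np.degrees(np.arctan2(a[0] * v[1] - a[1] * v[0], np.dot(a, v)))
        if abs(bearing) <= sector_half:
            any_anterior = True
    if any_anterior:
        cat = "anterior"
    elif n_membrane:
        cat = "membrane_other"
    else:
        cat = "none"
    return PkRecord(outline.cell_id, cat, n_puncta=len(pts), n_membrane=n_membrane)


def score_pk_cells(outlines, puncta_by_cell: dict, **kwargs) -> pd.DataFrame:
    """Score many cells; ``puncta_by_cell`` maps cell_id -> (n, 2) points."""
    recs = [
        score_pk_localization(o, puncta_by_cell.get(o.cell_id, []), **kwargs)
        for o in outlines
    ]
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in recs],
            "category": [r.category for r in recs],
            "n_puncta": [r.n_puncta for r in recs],
            "n_membrane": [r.n_membrane for r in recs],
        }
    )
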