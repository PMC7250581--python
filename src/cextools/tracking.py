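"""Nuclear detection and track linking for time-lapse movies.

Detection is a Laplacian-of-Gaussian blob detector (scale-normalized
response at one spot scale, 3x3 local maxima above threshold, sub-pixel
centroid by center of mass of the response in a 3-pixel window). Linking
is greedy mutual-nearest-neighbor between consecutive frames with a hard
displacement gate: no gap closing, no splitting/merging, so the output is
deterministic and independent of detection enumeration order (detections
are sorted lexicographically by centroid before matching; argmin ties
then resolve to the lexicographically smallest partner).

When a 4D (t, z, y, x) movie is supplied with ``project=True``, frames are
maximum-intensity projected before 2D detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi


@dataclass(frozen=True)
class Detection:
    """A detected nucleus in one frame (centroid in micrometres)."""

    frame: int
    centroid: tuple[float, ...]
    response: float


class MetadataError(ValueError):
    """Raised when required image metadata (pixel size) is missing."""


def _detect_frame(img: np.ndarray, pixel_size: float, sigma_um: float, threshold: float):
    sig_px = sigma_um / pixel_size
    # scale-normalized LoG; bright blobs give positive peaks
    resp = -(sig_px**2) * ndi.gaussian_laplace(img.astype(float), sig_px)
    maxima = (resp == ndi.maximum_filter(resp, size=3)) & (resp > threshold)
    coords = np.argwhere(maxima)
    out = []
    for rc in coords:
        r, c = int(rc[0]), int(rc[1])
        r0, r1 = max(0, r - 1), min(img.shape[0], r + 2)
        c0, c1 = max(0, c - 1), min(img.shape[1], c + 2)
        w = np.clip(resp[r0:r1, c0:c1], 0.0, None)
        tot = w.sum()
        if tot <= 0:
            rr, cc = float(r), float(c)
        else:
            rr_idx, cc_idx = np.mgrid[r0:r1, c0:c1]
            rr = float((rr_idx * w).sum() / tot)
            cc = float((cc_idx * w).sum() / tot)
        out.append((cc * pixel_size, rr * pixel_size, float(resp[r, c])))
    return out


def detect_nuclei(
    movie: np.ndarray,
    pixel_size_um: float,
    sigma_um: float,
    threshold: float,
    origin_xy: tuple[float, float] = (0.0, 0.0),
    project: bool = True,
) -> list[list[Detection]]:
    """Detect nuclei in every frame of a (t, y, x) or (t, z, y, x) movie.

    ``origin_xy`` maps pixel space back to analysis coordinates (see
    :func:`cextools.synthetic.render_track_movie`). Returns one Detection
    list per frame.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise MetadataError("pixel size metadata missing or invalid")
    if sigma_um <= 0:
        raise ValueError("sigma must be positive")
    movie = np.asarray(movie)
    if movie.ndim == 4:
        if not project:
            raise NotImplementedError("3D linking is disabled; enable projection")
        movie = movie.max(axis=1)
    if movie.ndim != 3:
        raise ValueError("movie must be (t, y, x) or (t, z, y, x)")
    ox, oy = origin_xy
    per_frame: list[list[Detection]] = []
    for f in range(movie.shape[0]):
        dets = [
            Detection(f, (ox + x, oy + y), resp)
            for x, y, resp in _detect_frame(movie[f], pixel_size_um, sigma_um, threshold)
        ]
        per_frame.append(dets)
    return per_frame


def _mutual_nn_links(pa: np.ndarray, pb: np.ndarray, max_disp: float):
    """Indices (i, j) of mutual nearest neighbors closer than max_disp."""
    if len(pa) == 0 or len(pb) == 0:
        return []
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    fwd = d.argmin(axis=1)
    bwd = d.argmin(axis=0)
    links = []
    for i, j in enumerate(fwd):
        if bwd[j] == i and d[i, j] <= max_disp:
            links.append((i, int(j)))
    return links


def link_tracks(
    detections: list[list[Detection]],
    max_disp: float,
    min_track_len: int = 2,
    dt_min: float = 5.0,
) -> pd.DataFrame:
    """Link per-frame detections into tracks by mutual nearest neighbors.

    Links longer than ``max_disp`` (um per frame) are forbidden; unlinked
    detections start new tracks; tracks shorter than ``min_track_len``
    frames are dropped. Returns a track table (track_id, frame, time_min,
    x_um, y_um) with consecutive frames within each track.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    # sort detections within each frame for order-independence
    frames = [sorted(dets, key=lambda d: d.centroid) for dets in detections]
    tracks: list[list[Detection]] = []
    active: dict[int, int] = {}  # detection index in current frame -> track index
    for f, dets in enumerate(frames):
        if f == 0:
            for i, det in enumerate(dets):
                tracks.append([det])
                active[i] = len(tracks) - 1
            continue
        prev = frames[f - 1]
        pa = np.array([d.centroid for d in prev], dtype=float).reshape(len(prev), -1)
        pb = np.array([d.centroid for d in dets], dtype=float).reshape(len(dets), -1)
        links = _mutual_nn_links(pa, pb, max_disp)
        new_active: dict[int, int] = {}
        linked_b = set()
        for i, j in links:
            if i in active:
                t = active[i]
                tracks[t].append(dets[j])
                new_active[j] = t
                linked_b.add(j)
        for j, det in enumerate(dets):
            if j not in linked_b:
                tracks.append([det])
                new_active[j] = len(tracks) - 1
        active = new_active
    kept = [t for t in tracks if len(t) >= min_track_len]
    kept.sort(key=lambda t: (t[0].frame, t[0].centroid))
    rows = []
    for tid, tr in enumerate(kept):
        for det in tr:
            row = {
                "track_id": tid,
                "frame": det.frame,
                "time_min": det.frame * dt_min,
                "x_um": det.centroid[0],
                "y_um": det.centroid[1],
            }
            if len(det.centroid) == 3:
                row["z_um"] = det.centroid[2]
            rows.append(row)
    cols = ["track_id", "frame", "time_min", "x_um", "y_um"]
    if rows and "z_um" in rows[0]:
        cols.append("z_um")
    return pd.DataFrame(rows, columns=cols)
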