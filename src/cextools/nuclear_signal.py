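"""3D nuclear segmentation, per-nucleus signal measurement, positive
calling, and signal-asymmetry testing along an explant axis.

The DAPI channel is binarized (Otsu by default), 26-connected components
become nucleus masks, and components outside a physical volume window are
discarded. Mean signal intensity is then measured over each nucleus's
voxels, positives are called against a background threshold (three
strategies exposed), and each nucleus is assigned a normalized position
p in [0, 1] along the explant's principal axis, oriented so the
high-signal end maps to p < 0.5. Asymmetry is read out as a two-sample
K-S test of p among positive nuclei against p among all nuclei.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .stats import ks_two_sample

#: default physical volume filter for zebrafish-scale nuclei
VMIN_UM3 = 30.0
VMAX_UM3 = 1500.0

_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class AsymmetryResult:
    """Asymmetry readout for one explant."""

    n_total: int
    n_positive: int
    median_p_positive: float | None
    ks_D: float | None
    ks_p: float | None
    threshold: float | None = None
    unoriented: bool = False


def segment_nuclei_3d(
    dapi: np.ndarray,
    voxel_size_um,
    threshold_method: str = "otsu",
    absolute_threshold: float | None = None,
    vmin_um3: float = VMIN_UM3,
    vmax_um3: float = VMAX_UM3,
):
    """Segment nuclei from a (z, y, x) DAPI stack.

    Returns (nuclei, labels): a DataFrame with nucleus_id, centroid in
    micrometres, volume and mean DAPI per nucleus, and the labeled stack
    (needed by :func:`measure_nuclear_signal`). Components with volumes
    outside [vmin_um3, vmax_um3] are removed from both.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 3:
        raise ValueError("DAPI stack must be 3D (z, y, x)")
    voxel = np.asarray(voxel_size_um, dtype=float)
    if voxel.shape != (3,) or np.any(voxel <= 0):
        raise ValueError("voxel_size_um must be three positive lengths (z, y, x)")
    if threshold_method == "otsu":
        if dapi.max() == dapi.min():
            warnings.warn("uniform DAPI stack: no nuclei segmented", stacklevel=2)
            return _empty_nuclei(), np.zeros(dapi.shape, dtype=np.int32)
        thr = threshold_otsu(dapi)
    elif threshold_method == "absolute":
        if absolute_threshold is None:
            raise ValueError("absolute threshold_method requires absolute_threshold")
        thr = float(absolute_threshold)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    mask = dapi > thr
    labels, n = ndi.label(mask, structure=_CONN26)
    if n == 0:
        warnings.warn("empty DAPI mask: no nuclei segmented", stacklevel=2)
        return _empty_nuclei(), labels.astype(np.int32)
    voxel_vol = float(np.prod(voxel))
    idx = np.arange(1, n + 1)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    volumes = counts * voxel_vol
    keep = (volumes >= vmin_um3) & (volumes <= vmax_um3)
    # relabel surviving components compactly
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[idx[keep]] = np.arange(1, keep.sum() + 1)
    labels = remap[labels]
    kept_idx = idx[keep]
    if len(kept_idx) == 0:
        return _empty_nuclei(), labels
    centroids = ndi.center_of_mass(dapi, labels, np.arange(1, keep.sum() + 1))
    mean_dapi = ndi.mean(dapi, labels, np.arange(1, keep.sum() + 1))
    cz, cy, cx = np.array(centroids).T * voxel[:, None]
    return (
        pd.DataFrame(
            {
                "nucleus_id": np.arange(keep.sum()),
                "x_um": cx,
                "y_um": cy,
                "z_um": cz,
                "volume_um3": volumes[keep],
                "mean_dapi": mean_dapi,
            }
        ),
        labels,
    )


def _empty_nuclei() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["nucleus_id", "x_um", "y_um", "z_um", "volume_um3", "mean_dapi"]
    )


def measure_nuclear_signal(
    nuclei: pd.DataFrame, labels: np.ndarray, signal: np.ndarray
) -> pd.DataFrame:
    """Add per-nucleus mean signal intensity (over each nucleus's voxels)."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape != labels.shape:
        raise ValueError(
            f"signal stack shape {signal.shape} does not match segmentation {labels.shape}"
        )
    out = nuclei.copy()
    if len(out) == 0:
        out["mean_signal"] = pd.Series(dtype=float)
        return out
    out["mean_signal"] = ndi.mean(signal, labels, out.nucleus_id.to_numpy() + 1)
    return out


def call_positive(
    nuclei: pd.DataFrame,
    strategy: str = "control_percentile",
    control=None,
    percentile: float = 97.5,
    k_mad: float = 3.0,
    threshold: float | None = None,
):
    """Flag signal-positive nuclei against a background threshold.

    Strategies: control_percentile (default) thresholds at the given
    percentile of a control sample's mean signals; robust_z at
    median + k_mad * MAD of the sample itself; absolute at a user value.
    Returns (nuclei with a ``positive`` column, threshold used).
    """
    vals = nuclei.mean_signal.to_numpy(dtype=float)
    if strategy == "control_percentile":
        if control is None:
            raise ValueError("control_percentile strategy requires a control sample")
        ctrl = np.asarray(control, dtype=float).ravel()
        if ctrl.size == 0:
            raise ValueError("control sample is empty")
        thr = float(np.percentile(ctrl, percentile))
    elif strategy == "robust_z":
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        thr = float(med + k_mad * mad)
    elif strategy == "absolute":
        if threshold is None:
            raise ValueError("absolute strategy requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown positivity strategy {strategy!r}")
    out = nuclei.copy()
    out["positive"] = vals > thr
    return out, thr


def orient_and_position(nuclei: pd.DataFrame, axis=None, tie_tol: float = 0.01):
    """Assign each nucleus a normalized position p in [0, 1] along the
    explant axis, oriented so the high-signal end maps to p < 0.5.

    The axis is the first principal component of the centroid (x, y) cloud
    unless an explicit unit ``axis`` annotation is given. After min-max
    normalizing the projections, the signal-weighted mean position
    c = sum(s_i * p_i) / sum(s_i) decides orientation: c > 0.5 flips p to
    1 - p; |c - 0.5| < tie_tol keeps the default orientation and flags the
    explant as unoriented. Returns (nuclei with ``axis_position``, flipped,
    unoriented).
    """
    if len(nuclei) < 2:
        raise ValueError("need at least two nuclei to define an axis")
    pts = nuclei[["x_um", "y_um"]].to_numpy(dtype=float)
    if axis is not None:
        u = np.asarray(axis, dtype=float)
        u = u / np.linalg.norm(u)
    else:
        centered = pts - pts.mean(axis=0)
        cov = centered.T @ centered
        if np.allclose(cov, 0):
            raise ValueError("all centroids coincide: explant axis undefined")
        evals, evecs = np.linalg.eigh(cov)
        u = evecs[:, np.argmax(evals)]
    proj = pts @ u
    lo, hi = proj.min(), proj.max()
    if hi == lo:
        raise ValueError("all centroids project to one point: axis degenerate")
    p = (proj - lo) / (hi - lo)
    flipped = False
    unoriented = False
    if "mean_signal" in nuclei.columns and nuclei.mean_signal.sum() > 0:
        s = nuclei.mean_signal.to_numpy(dtype=float)
        c = float((s * p).sum() / s.sum())
        if abs(c - 0.5) < tie_tol:
            unoriented = True
        elif c > 0.5:
            p = 1.0 - p
            flipped = True
    else:
        unoriented = True
    out = nuclei.copy()
    out["axis_position"] = p
    return out, flipped, unoriented


def asymmetry_test(nuclei: pd.DataFrame, unoriented: bool = False) -> AsymmetryResult:
    """K-S test of axis positions of positive nuclei against all nuclei."""
    if "axis_position" not in nuclei.columns:
        raise ValueError("run orient_and_position first")
    n_total = len(nuclei)
    pos = nuclei[nuclei.positive]
    if len(pos) == 0:
        warnings.warn("no positive nuclei: asymmetry test skipped", stacklevel=2)
        return AsymmetryResult(n_total, 0, None, None, None, unoriented=unoriented)
    res = ks_two_sample(pos.axis_position, nuclei.axis_position)
    return AsymmetryResult(
        n_total=n_total,
        n_positive=len(pos),
        median_p_positive=float(pos.axis_position.median()),
        ks_D=res.statistic,
        ks_p=res.p,
        unoriented=unoriented,
    )


def analyze_explant(
    dapi: np.ndarray,
    signal: np.ndarray,
    voxel_size_um,
    control_signals=None,
    strategy: str = "control_percentile",
    **kwargs,
):
    """End-to-end asymmetry analysis of one explant.

    Segments nuclei from DAPI, measures the signal channel, calls positives
    (against ``control_signals`` under the default strategy), assigns axis
    positions and runs the asymmetry test. Returns (nuclei table,
    AsymmetryResult).
    """
    seg_kwargs = {
        k: kwargs.pop(k)
        for k in ("threshold_method", "absolute_threshold", "vmin_um3", "vmax_um3")
        if k in kwargs
    }
    nuclei, labels = segment_nuclei_3d(dapi, voxel_size_um, **seg_kwargs)
    if len(nuclei) < 2:
        warnings.warn("fewer than two nuclei segmented: no asymmetry readout", stacklevel=2)
        return nuclei, AsymmetryResult(len(nuclei), 0, None, None, None)
    nuclei = measure_nuclear_signal(nuclei, labels, signal)
    nuclei, thr = call_positive(nuclei, strategy=strategy, control=control_signals, **kwargs)
    nuclei, _, unoriented = orient_and_position(nuclei)
    result = asymmetry_test(nuclei, unoriented=unoriented)
    result.threshold = thr
    return nuclei, result
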