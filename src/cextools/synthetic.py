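"""Synthetic-data generators emulating the statistical structure of
convergence-extension imaging data, with exact ground truth.

Every generator here produces one of the pipeline's input types together
with a ground-truth record keyed to it, so each analysis stage can be
tested without microscopy data:

* ``simulate_mib_tracks`` — nuclei advected by the minimal linear velocity
  field with a stationary point and distance-proportional speed (the
  kinematic signature of mediolateral intercalation): per Euler step of
  size ``dt`` minutes,

      x <- x - a*x*dt - w*y*dt + eps_x
      y <- y + b*y*dt + w*x*dt + eps_y,   eps ~ Normal(0, sigma^2),

  where ``a`` is the convergence rate, ``b`` the extension rate and ``w``
  an optional swirl that produces disordered, midline-crossing mutant-like
  paths. With sigma = 0 and w = 0 the per-track displacement has the exact
  closed form dx = x0 * ((1 - a*dt)^n - 1), dy = y0 * ((1 + b*dt)^n - 1).
* ``simulate_cell_field`` — elliptical cell outlines whose (undirected)
  major-axis orientations follow a doubled-angle von Mises law around the
  ML axis (kappa = 0 gives the uniform, unpolarized control).
* ``simulate_protrusions`` — protrusion angles on the full circle:
  ML-bipolar, uniform, or weakly anterior-biased.
* ``simulate_nuclear_stack`` — two-channel 3D stacks of Gaussian-blob
  nuclei with a constant DAPI amplitude and a per-nucleus signal amplitude
  following a flat / linear / sigmoid profile along x (high on the left).
* ``simulate_pk_cells`` — cells with membrane puncta placed in the
  anterior sector, elsewhere on the membrane, or absent.
* ``simulate_explant_shape`` — constant-width explant silhouettes around a
  straight or circular-arc midline.

Defaults mirror the imaging conditions the analyses assume: 5-minute
frames for 36 steps (a 3-hour time-lapse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphometry import ExplantShape
from .polarity import CellOutline, GeometryError


class StabilityError(ValueError):
    """Raised when the Euler step would overshoot the stationary point."""


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed at the requested separation."""


# ---------------------------------------------------------------------------
# track kinematics


@dataclass(frozen=True)
class MIBFieldConfig:
    """Parameters of the synthetic convergence/extension kinematic field.

    Rates are per minute; ``noise_sigma`` is the per-step positional jitter
    in micrometres. The stability condition a*dt < 1 keeps the convergence
    update from overshooting the midline.
    """

    n_cells: int = 200
    domain_half_width: float = 250.0
    domain_half_height: float = 250.0
    conv_rate: float = 0.002   # a, 1/min
    ext_rate: float = 0.002    # b, 1/min
    swirl_rate: float = 0.0    # w, 1/min (any sign)
    noise_sigma: float = 0.5   # um per step
    dt: float = 5.0            # minutes
    n_steps: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.conv_rate, self.ext_rate, self.noise_sigma) < 0:
            raise ValueError("rates and noise must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("need at least one step")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if self.conv_rate * self.dt >= 1:
            raise StabilityError(
                f"a*dt = {self.conv_rate * self.dt:.3g} >= 1: convergence step unstable"
            )

    @property
    def ml_displacement_factor(self) -> float:
        """Noiseless closed-form dx/x0 over the whole movie (w = 0)."""
        return (1.0 - self.conv_rate * self.dt) ** self.n_steps - 1.0

    @property
    def ap_displacement_factor(self) -> float:
        """Noiseless closed-form dy/y0 over the whole movie (w = 0)."""
        return (1.0 + self.ext_rate * self.dt) ** self.n_steps - 1.0


@dataclass
class MIBGroundTruth:
    """Ground truth for a simulated track table."""

    start_positions: pd.DataFrame      # track_id, x0_um, y0_um
    ml_displacement_factor: float
    ap_displacement_factor: float
    noiseless_tracks: pd.DataFrame     # same schema as the track table


def simulate_mib_tracks(config: MIBFieldConfig) -> tuple[pd.DataFrame, MIBGroundTruth]:
    """Simulate nuclei advected by the linear convergence/extension field.

    Returns a track table (track_id, frame, time_min, x_um, y_um) and the
    ground truth: starting positions, the closed-form displacement factors,
    and the noiseless trajectories under the same swirl.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    x = rng.uniform(-config.domain_half_width, config.domain_half_width, n)
    y = rng.uniform(-config.domain_half_height, config.domain_half_height, n)
    a, b, w, dt = config.conv_rate, config.ext_rate, config.swirl_rate, config.dt

    def step(px, py, noisy):
        nx = px - a * px * dt - w * py * dt
        ny = py + b * py * dt + w * px * dt
        if noisy and config.noise_sigma > 0:
            nx = nx + rng.normal(0.0, config.noise_sigma, n)
            ny = ny + rng.normal(0.0, config.noise_sigma, n)
        return nx, ny

    frames = [np.stack([x.copy(), y.copy()], axis=1)]
    clean = [frames[0].copy()]
    cx, cy = x.copy(), y.copy()
    for _ in range(config.n_steps):
        x, y = step(x, y, noisy=True)
        cx, cy = step(cx, cy, noisy=False)
        frames.append(np.stack([x, y], axis=1))
        clean.append(np.stack([cx, cy], axis=1))

    def to_table(snapshots):
        recs = []
        for f, snap in enumerate(snapshots):
            recs.append(
                pd.DataFrame(
                    {
                        "track_id": np.arange(n),
                        "frame": f,
                        "time_min": f * dt,
                        "x_um": snap[:, 0],
                        "y_um": snap[:, 1],
                    }
                )
            )
        return (
            pd.concat(recs, ignore_index=True)
            .sort_values(["track_id", "frame"])
            .reset_index(drop=True)
        )

    tracks = to_table(frames)
    truth = MIBGroundTruth(
        start_positions=pd.DataFrame(
            {"track_id": np.arange(n), "x0_um": frames[0][:, 0], "y0_um": frames[0][:, 1]}
        ),
        ml_displacement_factor=config.ml_displacement_factor,
        ap_displacement_factor=config.ap_displacement_factor,
        noiseless_tracks=to_table(clean),
    )
    return tracks, truth


def render_track_movie(
    tracks: pd.DataFrame,
    pixel_size_um: float = 1.0,
    spot_sigma_um: float = 2.0,
    amplitude: float = 100.0,
    noise_sd: float = 0.0,
    pad_um: float = 15.0,
    seed: int = 0,
):
    """Render a track table into a 2D time-lapse of Gaussian nuclear spots.

    Bridges the point simulator and the image-based tracker: each frame is a
    (rows, cols) image with a Gaussian spot of peak ``amplitude`` at every
    nucleus, plus optional Gaussian read noise (SNR = amplitude/noise_sd).
    Returns (movie, origin_xy) where origin_xy maps pixel (row, col) back to
    analysis coordinates via x = origin_x + col*px, y = origin_y + row*px.
    """
    rng = np.random.default_rng(seed)
    xmin = tracks.x_um.min() - pad_um
    ymin = tracks.y_um.min() - pad_um
    ncols = int(np.ceil((tracks.x_um.max() + pad_um - xmin) / pixel_size_um)) + 1
    nrows = int(np.ceil((tracks.y_um.max() + pad_um - ymin) / pixel_size_um)) + 1
    n_frames = int(tracks.frame.max()) + 1
    movie = np.zeros((n_frames, nrows, ncols), dtype=float)
    sig_px = spot_sigma_um / pixel_size_um
    win = int(np.ceil(4 * sig_px))
    for f, grp in tracks.groupby("frame"):
        img = movie[int(f)]
        for _, row in grp.iterrows():
            c = (row.x_um - xmin) / pixel_size_um
            r = (row.y_um - ymin) / pixel_size_um
            r0, r1 = max(0, int(r) - win), min(nrows, int(r) + win + 1)
            c0, c1 = max(0, int(c) - win), min(ncols, int(c) + win + 1)
            rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            img[r0:r1, c0:c1] += amplitude * np.exp(
                -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sig_px**2)
            )
    if noise_sd > 0:
        movie = movie + rng.normal(0.0, noise_sd, movie.shape)
    return movie, (float(xmin), float(ymin))


# ---------------------------------------------------------------------------
# cell fields and protrusions


@dataclass
class CellFieldTruth:
    """True orientations/aspect ratios behind a simulated cell field."""

    table: pd.DataFrame  # cell_id, theta_deg, aspect_ratio


def _sample_axial_von_mises(rng, n: int, kappa: float) -> np.ndarray:
    """Undirected orientations in [0, 180) deg, concentrated on the ML axis.

    Uses the doubled-angle construction: draw 2*theta from von Mises(0,
    kappa) so that theta and theta+180 are identified; kappa = 0 reduces to
    the uniform law on [0, 180).
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return rng.uniform(0.0, 180.0, n)
    doubled = rng.vonmises(0.0, kappa, n)  # radians in (-pi, pi]
    return (np.degrees(doubled) / 2.0) % 180.0


def _ellipse_polygon(center, theta_deg, semi_major, semi_minor, n_vertices):
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    pts = np.stack([semi_major * np.cos(t), semi_minor * np.sin(t)], axis=1)
    th = np.radians(theta_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return pts @ rot.T + np.asarray(center, dtype=float)


def simulate_cell_field(
    n: int,
    kappa: float,
    ar_mean: float = 1.8,
    ar_sd: float = 0.4,
    seed: int = 0,
    n_vertices: int = 64,
    cell_radius_um: float = 5.0,
) -> tuple[list[CellOutline], CellFieldTruth]:
    """Simulate a field of elliptical cells with axial von Mises orientations.

    Aspect ratios are drawn Normal(ar_mean, ar_sd) and floored at 1; each
    cell is emitted as an ``n_vertices``-gon sampled on the ellipse with that
    orientation and ratio (area held at pi * cell_radius_um^2). Cells are
    laid out on a non-overlapping grid; positions carry no signal.
    """
    if ar_mean < 1:
        raise ValueError("mean aspect ratio must be >= 1")
    if n < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    thetas = _sample_axial_von_mises(rng, n, kappa)
    ars = np.maximum(1.0, rng.normal(ar_mean, ar_sd, n))
    ncols = int(np.ceil(np.sqrt(n)))
    spacing = 6.0 * cell_radius_um * max(1.0, np.sqrt(ars.max()))
    outlines = []
    for i in range(n):
        center = ((i % ncols) * spacing, (i // ncols) * spacing)
        a_semi = cell_radius_um * np.sqrt(ars[i])
        b_semi = cell_radius_um / np.sqrt(ars[i])
        verts = _ellipse_polygon(center, thetas[i], a_semi, b_semi, n_vertices)
        outlines.append(CellOutline(cell_id=i, vertices=verts))
    truth = CellFieldTruth(
        pd.DataFrame({"cell_id": np.arange(n), "theta_deg": thetas, "aspect_ratio": ars})
    )
    return outlines, truth


def simulate_protrusions(
    n: int, mode: str = "bipolar_ml", kappa: float = 5.0, seed: int = 0
) -> np.ndarray:
    """Protrusion angles in degrees on [0, 360).

    bipolar_ml: equal mixture of von Mises at 0 and 180 deg (the strong ML
    bias of intercalating cells); uniform: isotropic control;
    anterior_biased: von Mises centered on anterior (90 deg) — pass a small
    kappa for the 'slight anterior bias' of unpolarized mutant cells.
    """
    if n < 1:
        raise ValueError("need at least one protrusion")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        return rng.uniform(0.0, 360.0, n)
    if mode == "bipolar_ml":
        centers = rng.choice([0.0, 180.0], n)
        return (centers + np.degrees(rng.vonmises(0.0, kappa, n))) % 360.0
    if mode == "anterior_biased":
        return (90.0 + np.degrees(rng.vonmises(0.0, kappa, n))) % 360.0
    raise ValueError(f"unknown protrusion mode {mode!r}")


# ---------------------------------------------------------------------------
# 3D nuclear stacks


@dataclass(frozen=True)
class StackConfig:
    """Parameters of a synthetic two-channel 3D nuclear stack.

    ``shape``/``voxel_size`` are (z, y, x). Nuclei are isotropic Gaussian
    blobs of scale ``nucleus_sigma`` (um) placed with pairwise separation of
    at least ``min_separation`` (must exceed 2*nucleus_sigma so blobs stay
    resolvable). The DAPI amplitude is constant; the signal amplitude per
    nucleus follows ``signal_gradient_kind`` along x — "flat" uses
    ``gradient_low`` everywhere, "linear"/"sigmoid" run from
    ``gradient_high`` at the left (x = 0) face to ``gradient_low`` at the
    right. On top of the spatial profile each nucleus's signal amplitude
    carries a multiplicative lognormal factor of coefficient of variation
    ``amplitude_cv``, emulating nucleus-to-nucleus staining variability
    (immunostain background is far more variable than read noise). The
    ground-truth positivity level is the midpoint of low/high, compared
    against the realized (read-noise-free) amplitude.
    """

    shape: tuple[int, int, int] = (24, 48, 96)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_nuclei: int = 300
    nucleus_sigma: float = 2.0
    min_separation: float = 7.0
    dapi_amplitude: float = 200.0
    signal_gradient_kind: str = "flat"
    gradient_low: float = 40.0
    gradient_high: float = 160.0
    noise_sd: float = 5.0
    amplitude_cv: float = 0.2
    seed: int = 0
    max_placement_tries: int = 10_000

    def __post_init__(self) -> None:
        if self.min_separation <= 2 * self.nucleus_sigma:
            raise ValueError("min_separation must exceed 2*nucleus_sigma")
        if min(self.dapi_amplitude, self.gradient_low, self.gradient_high,
               self.noise_sd, self.amplitude_cv) < 0:
            raise ValueError("amplitudes and noise must be non-negative")
        if self.signal_gradient_kind not in ("flat", "linear", "sigmoid"):
            raise ValueError(f"unknown gradient kind {self.signal_gradient_kind!r}")


@dataclass
class StackTruth:
    """Ground truth for a synthetic nuclear stack."""

    nuclei: pd.DataFrame   # nucleus_id, x_um, y_um, z_um, signal_amplitude, positive
    positive_level: float


def _signal_amplitude(cfg: StackConfig, x_norm: np.ndarray) -> np.ndarray:
    lo, hi = cfg.gradient_low, cfg.gradient_high
    if cfg.signal_gradient_kind == "flat":
        return np.full_like(x_norm, lo)
    if cfg.signal_gradient_kind == "linear":
        return hi + (lo - hi) * x_norm
    # sigmoid step, high on the left, width ~10% of the axis
    return lo + (hi - lo) / (1.0 + np.exp((x_norm - 0.5) / 0.1))


def _place_nuclei(cfg: StackConfig, rng) -> np.ndarray:
    """Rejection-sample centroids (z, y, x in um) with minimum separation."""
    extent = np.array(cfg.shape) * np.array(cfg.voxel_size)
    margin = 2.0 * cfg.nucleus_sigma
    if np.any(extent <= 2 * margin):
        raise PlacementError("stack too small for the nucleus size")
    placed = np.empty((0, 3))
    tries = 0
    while len(placed) < cfg.n_nuclei:
        if tries >= cfg.max_placement_tries:
            raise PlacementError(
                f"placed only {len(placed)}/{cfg.n_nuclei} nuclei after "
                f"{tries} tries at separation {cfg.min_separation} um"
            )
        cand = rng.uniform(margin, extent - margin)
        tries += 1
        if len(placed) and np.min(np.linalg.norm(placed - cand, axis=1)) < cfg.min_separation:
            continue
        placed = np.vstack([placed, cand])
    return placed


def simulate_nuclear_stack(config: StackConfig):
    """Simulate matched DAPI and signal stacks plus ground truth.

    Returns (dapi, signal, truth): two float arrays of shape ``config.shape``
    (z, y, x) and a :class:`StackTruth` listing every nucleus's centroid,
    noiseless signal amplitude, and whether that amplitude exceeds the
    positivity level (midpoint of gradient low/high).
    """
    rng = np.random.default_rng(config.seed)
    centers = _place_nuclei(config, rng)  # (n, 3) as (z, y, x) um
    x_extent = config.shape[2] * config.voxel_size[2]
    x_norm = centers[:, 2] / x_extent
    amps = _signal_amplitude(config, x_norm)
    if config.amplitude_cv > 0:
        sig_ln = np.sqrt(np.log1p(config.amplitude_cv**2))
        amps = amps * rng.lognormal(-0.5 * sig_ln**2, sig_ln, len(amps))
    level = 0.5 * (config.gradient_low + config.gradient_high)

    dapi = np.zeros(config.shape, dtype=float)
    signal = np.zeros(config.shape, dtype=float)
    vz, vy, vx = config.voxel_size
    sig = config.nucleus_sigma
    win = 4.0 * sig
    for (cz, cy, cx), amp in zip(centers, amps):
        z0, z1 = max(0, int((cz - win) / vz)), min(config.shape[0], int((cz + win) / vz) + 2)
        y0, y1 = max(0, int((cy - win) / vy)), min(config.shape[1], int((cy + win) / vy) + 2)
        x0, x1 = max(0, int((cx - win) / vx)), min(config.shape[2], int((cx + win) / vx) + 2)
        zz = (np.arange(z0, z1) * vz - cz)[:, None, None]
        yy = (np.arange(y0, y1) * vy - cy)[None, :, None]
        xx = (np.arange(x0, x1) * vx - cx)[None, None, :]
        blob = np.exp(-(zz**2 + yy**2 + xx**2) / (2.0 * sig**2))
        dapi[z0:z1, y0:y1, x0:x1] += config.dapi_amplitude * blob
        signal[z0:z1, y0:y1, x0:x1] += amp * blob
    if config.noise_sd > 0:
        dapi = np.clip(dapi + rng.normal(0, config.noise_sd, config.shape), 0, None)
        signal = np.clip(signal + rng.normal(0, config.noise_sd, config.shape), 0, None)
    truth = StackTruth(
        nuclei=pd.DataFrame(
            {
                "nucleus_id": np.arange(len(centers)),
                "x_um": centers[:, 2],
                "y_um": centers[:, 1],
                "z_um": centers[:, 0],
                "signal_amplitude": amps,
                "positive": amps > level,
            }
        ),
        positive_level=level,
    )
    return dapi, signal, truth


# ---------------------------------------------------------------------------
# Prickle-GFP cells and explant shapes


@dataclass
class PkTruth:
    """True localization categories behind a simulated Pk-GFP field."""

    table: pd.DataFrame  # cell_id, category


def simulate_pk_cells(
    n: int,
    p_anterior: float,
    p_membrane_other: float,
    seed: int = 0,
    n_vertices: int = 64,
    cell_radius_um: float = 5.0,
    puncta_per_cell: int = 2,
):
    """Simulate cells with membrane puncta in known localization categories.

    Each cell is assigned anterior / membrane_other / none with the stated
    probabilities. Anterior cells get puncta on boundary vertices within
    ~40 deg of the anterior direction (+y); membrane_other cells get puncta
    well outside the anterior sector; "none" cells get no puncta. Returns
    (outlines, puncta_by_cell, truth).
    """
    if p_anterior < 0 or p_membrane_other < 0 or p_anterior + p_membrane_other > 1:
        raise ValueError("category probabilities must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    outlines, _ = simulate_cell_field(
        n, kappa=0.0, ar_mean=1.3, ar_sd=0.15,
        seed=int(rng.integers(2**31)), n_vertices=n_vertices,
        cell_radius_um=cell_radius_um,
    )
    cats = rng.choice(
        ["anterior", "membrane_other", "none"],
        n,
        p=[p_anterior, p_membrane_other, 1.0 - p_anterior - p_membrane_other],
    )
    puncta_by_cell: dict[int, np.ndarray] = {}
    for o, cat in zip(outlines, cats):
        if cat == "none":
            continue
        centroid = o.vertices.mean(axis=0)
        rel = o.vertices - centroid
        # bearing of each vertex from anterior (+y), in degrees
        bearings = np.degrees(np.arctan2(-rel[:, 0], rel[:, 1]))
        if cat == "anterior":
            ok = np.abs(bearings) <= 40.0
        else:
            ok = np.abs(bearings) >= 55.0
        idx = rng.choice(np.flatnonzero(ok), size=puncta_per_cell, replace=True)
        puncta_by_cell[o.cell_id] = o.vertices[idx].copy()
    truth = PkTruth(pd.DataFrame({"cell_id": [o.cell_id for o in outlines], "category": cats}))
    return outlines, puncta_by_cell, truth


def simulate_explant_shape(
    midline_length: float, width: float, curvature: float = 0.0, seed: int = 0
) -> ExplantShape:
    """Constant-width explant silhouette around a straight or arced midline.

    The midline is a circular arc of the requested arc length and curvature
    (1/um; 0 gives a straight midline); the boundary offsets it by width/2
    on each side with flat end caps, so the true length/width ratio is
    exactly midline_length/width. ``seed`` is accepted for interface
    uniformity; the construction is deterministic.
    """
    del seed
    if midline_length <= 0 or width <= 0:
        raise GeometryError("midline length and width must be positive")
    if curvature < 0:
        raise GeometryError("curvature must be non-negative")
    n_pts = 201
    s = np.linspace(0.0, midline_length, n_pts)
    if curvature == 0.0:
        midline = np.stack([s, np.zeros_like(s)], axis=1)
        normals = np.tile([0.0, 1.0], (n_pts, 1))
    else:
        if curvature * midline_length >= np.pi:
            raise GeometryError("arc spans >= 180 degrees: degenerate silhouette")
        radius = 1.0 / curvature
        if width / 2.0 >= radius:
            raise GeometryError("width exceeds the arc's diameter of curvature")
        ang = s * curvature
        midline = np.stack([radius * np.sin(ang), radius * (1.0 - np.cos(ang))], axis=1)
        # inward normal points to the arc center (0, radius)
        normals = np.stack([-np.sin(ang), np.cos(ang)], axis=1)
    half = width / 2.0
    side_a = midline + half * normals
    side_b = midline - half * normals
    boundary = np.vstack([side_a, side_b[::-1]])
    return ExplantShape(boundary=boundary, midline=midline)
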