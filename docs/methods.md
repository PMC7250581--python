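# Methods

This note documents the models, conventions, defaults and known limits of
the package. Units are micrometres and minutes everywhere; the analysis
frame has +x mediolateral (ML, pointing right), +y anterior (AP), angles
counterclockwise from +x, and the dorsal midline registered to x = 0.

## The kinematic field and its closed forms

The synthetic track generator uses the minimal linear velocity field with
a stationary point and speed proportional to distance — the kinematic
signature of mediolateral intercalation. Per Euler step of size dt:

    x ← x − a·x·dt − ω·y·dt + ε_x
    y ← y + b·y·dt + ω·x·dt + ε_y,     ε ~ N(0, σ²) per axis,

with convergence rate a ≥ 0, extension rate b ≥ 0 (per minute), swirl
ω (any sign), and per-step jitter σ (μm). The update is applied
simultaneously from the previous position. With σ = ω = 0 the per-track
displacement is exact:

    Δx = x₀·[(1 − a·dt)ⁿ − 1],   Δy = y₀·[(1 + b·dt)ⁿ − 1],

so OLS of Δx on x₀ recovers the bracketed factor with R² = 1; these
closed forms are the ground truth every kinematics test checks against.
The stability condition a·dt < 1 is enforced at construction (an
overshooting Euler step would cross the midline unphysically). A nonzero
ω produces swirling, midline-crossing trajectories that mimic the
disorganized movement of Nodal-deficient mutants; because the rotation is
antisymmetric between axes, the per-axis regressions lose their slope and
R², which is exactly the mutant phenomenology the readout is meant to
distinguish.

Defaults: dt = 5 min, n = 36 steps (a 3-hour time-lapse at standard
cadence), a = b = 0.002/min (a·dt = 0.01: ~30% convergence over the
movie, a realistic gastrulation-scale rate), σ = 0.5 μm/step, 200 cells
in a 500 × 500 μm dorsal field. The field-of-view geometry and cell
density are not biologically constrained choices; they are configurable
and all results are reported against them.

## Orientation statistics

Cell axes are undirected (θ ≡ θ + 180°), so orientations are sampled by
the doubled-angle construction: 2θ ~ von Mises(0, κ), giving the axial
von Mises family on [0°, 180°) with the uniform law at κ = 0. Alignment
is the fold α = min(θ mod 180, 180 − θ mod 180) ∈ [0°, 90°]. For a
uniform field the pooled sample median of α is 45° in expectation — the
basis of the control-explant reproduction in `scripts/acceptance.py`
(5 explants × 100 cells, median of the pooled median across 20 seeds;
sampling sd of a single pooled median is ≈ 2°).

Aspect ratios are Normal(mean 1.8, sd 0.4) floored at 1; cells are
emitted as 64-gons of the corresponding ellipse at fixed area, on a
non-overlapping grid (positions carry no signal).

## Ellipse fitting

Polygon area, centroid and central second moments are computed by the
exact shoelace (Green's theorem) formulas, so results are independent of
image resolution and vertex orientation. Orientation is
θ = ½·atan2(2μ₁₁, μ₂₀ − μ₀₂) mapped to [0°, 180°); aspect ratio is
√(λ_max/λ_min) of the moment matrix. This can differ from rasterized
fit-ellipse tools at the sub-degree level, which is accepted. Cells with
aspect ratio < 1 + ε (ε = 0.05) have no meaningful major axis; they are
flagged `reliable_orientation=False`, excluded from alignment summaries,
and counted.

## Protrusion classification

Two schemes are exposed. The quadrant scheme (default for two-category
comparisons, matching the rose-diagram quadrants) calls a protrusion ML
when its angular distance to the ML axis {0°, 180°} is < 45°, else AP;
the 45° boundary goes to AP. The sector scheme uses ±30° wedges about
each axis, so ML, AP and neither each cover 120° of the circle. The
describable alternative ("within 60° of horizontal") cannot coexist with
a 120° remainder — the ±30° wedges are the geometrically consistent
reading and are what the three-category fractions (1/3 each under
uniformity) assume. Circular histograms use half-open 20° bins.

## Tracking

Detection is a single-scale Laplacian-of-Gaussian detector: the
scale-normalized response −σ²∇²G at the spot scale, 3×3 local maxima
above an absolute response threshold, and sub-pixel centroids by center
of mass of the (positive) response in a 3-pixel window. Linking is greedy
mutual-nearest-neighbor between consecutive frames with a hard gate
(links longer than `max_disp` forbidden), no gap closing and no
splitting/merging — chosen for determinism: detections are sorted
lexicographically by centroid before matching, so output is independent
of enumeration order, and distance ties resolve to the lexicographically
smaller partner. Tracker parameters (spot scale, threshold, gate) have no
published reference values; they are explicit configuration, never
silently assumed. 4D movies are maximum-intensity projected before 2D
detection; 3D linking is not implemented.

## Nuclear signal asymmetry

DAPI stacks are binarized (Otsu default, absolute threshold optional),
labeled with 26-connectivity, and filtered to volumes in [30, 1500] μm³
(zebrafish-scale nuclei at the stated voxel sizes; configurable and
echoed into outputs). Mean signal is averaged over each nucleus's voxel
set. Positivity strategies: `control_percentile` (default; threshold at
the 97.5th percentile of a control sample's mean signals), `robust_z`
(median + 3·MAD of the sample itself), `absolute`. The explant axis is
the first principal component of the centroid (x, y) cloud (an explicit
axis annotation overrides PCA); projections are min-max normalized to
p ∈ [0, 1]. Orientation (which end is p = 0) follows the signal-weighted
mean position c = Σsᵢpᵢ/Σsᵢ: c > 0.5 flips p → 1 − p so the high-signal
end maps to p < 0.5; |c − 0.5| < 0.01 keeps the default orientation and
flags the explant "unoriented". (A literal comparison of half-sums is
ill-posed for odd small samples; the signal center of mass is the
well-defined equivalent.) Asymmetry is the two-sample K-S of p among
positives versus all nuclei, reported with the median p of positives.

The synthetic stacks place isotropic Gaussian nuclei (σ = 2 μm) by
rejection sampling with ≥ 7 μm pairwise separation (bounded at 10⁴
tries), constant DAPI amplitude, and a per-nucleus signal amplitude that
is flat, linear or sigmoid along x (high on the left). Each amplitude
additionally carries a multiplicative lognormal factor (CV 0.2) emulating
nucleus-to-nucleus staining variability — immunostain background varies
far more between nuclei than voxel read noise does, and without this the
control background distribution is unrealistically tight and a background
threshold loses its meaning. The asymmetric condition uses the sigmoid
profile (high-left half, background-right half): it reproduces the
observed structure of a minority of positive nuclei concentrated at one
end. A full-span linear profile whose floor equals the control background
instead makes nearly every nucleus exceed a background threshold, leaving
the positives-vs-all comparison without contrast — a property of the
readout worth knowing when designing controls. The default test explant
is a scaled-down (24, 48, 96)-voxel stack at 2 μm voxels with 300 nuclei,
large enough for hundreds of segmented nuclei per explant while keeping
simulation suites fast.

Nuclei closer than the resolvable separation can merge into one
26-connected component; no watershed splitting is attempted (the
generator guarantees nominal separation; clumped real data are out of
scope). End-to-end on flat controls the pipeline calls ~5% of explants
asymmetric at α = 0.05, i.e. the K-S readout is calibrated despite the
positives being a subset of all nuclei (a mild dependence that makes the
test slightly conservative at very small positive counts).

## Morphometrics

Explant length is the arc length of the annotated midline polyline
(curvature accounted for by construction); width is measured along the
perpendicular to the midline tangent at the exact arc-length midpoint,
between the two boundary intersections. If the perpendicular fails to
cross exactly twice (concave silhouettes), it is retried at ±5% arc
length and the offset is reported. The synthetic silhouette is a
constant-width band around a circular-arc midline (flat caps), so the
true L/W is exactly the requested length/width; arcs spanning ≥ 180° or
widths exceeding the diameter of curvature are rejected as degenerate.
Neural-plate width/length are Euclidean distances between named landmark
points; both measurements are rigid-transform invariant.

## Statistics

All tests are two-sided with no continuity corrections. K-S D is the
exact ECDF supremum over the pooled sample (ties evaluated at pooled
points); p is asymptotic by default with an exact small-sample option.
Mann-Whitney U counts pairs x < y plus half-ties, reports
min(U, n₁n₂ − U), and uses the tie-corrected normal approximation (an
all-tied pooled sample is reported as p = 1). Chi-square is the Pearson
statistic on the r×k table with df = (r−1)(k−1); zero expected counts
raise an error instructing category merge. Type-I error at α = 0.05 is
calibrated to 3–7% for all three tests over 2000 null simulations in the
acceptance suite.

## What the synthetic data does and does not show

The generators reproduce the statistical structure the analyses assume —
linear kinematic fields, axial von Mises orientations, categorical
punctum placement, Gaussian nuclei with monotone signal profiles,
constant-width silhouettes — with exact ground truth, deterministic
seeding (identical config + seed ⇒ bit-identical output), and complete
truth records (one entry per generated record). They do not attempt
photorealism: no membrane-channel rendering, no optical PSF or
depth-dependent attenuation, no cell packing or mechanics, no curved
embryo surface (tracks are planar), and no nucleus shape variation.
Passing tests therefore demonstrate the correctness and calibration of
the measurement code under the assumed statistical structure, not
robustness to every artifact of real microscopy; on real data the
annotation and registration steps (midline at x = 0, AP axis aligned)
remain the analyst's responsibility.
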