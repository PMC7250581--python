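# cextools

Quantitative analysis of **convergence and extension (C&E)** cell behaviors
in zebrafish gastrulae and blastoderm explants: automated nuclear tracking
and displacement-gradient kinematics, planar-cell-polarity readouts
(elongation, mediolateral alignment, protrusion orientation, Prickle-GFP
localization), 3D nuclear signal asymmetry (pSmad2-style immunostains), and
explant/neural-plate morphometrics — together with a synthetic-data
generator that emulates the statistical structure of every input, so the
whole pipeline is testable without microscopy data.

Intended users are developmental biologists and image analysts who have
tracked nuclei, outlined cells, annotated protrusions or landmarks, or
collected two-channel 3D stacks, and want reproducible, scriptable versions
of the standard C&E measurements.

## What it computes

**Kinematics.** During C&E, cells converge toward the dorsal midline while
the tissue extends along the anteroposterior (AP) axis. With the midline
registered to x = 0 (+x mediolateral, +y anterior, μm and minutes
throughout), each track contributes a net displacement (Δx, Δy) and the
per-axis regression of displacement on starting position,

    Δx = s_ML · x₀ + c,   Δy = s_AP · y₀ + c′,

reads out convergence (s_ML < 0) and extension (s_AP > 0). A mediolateral
intercalation-like flow with convergence rate *a* and extension rate *b*
(per minute) gives the exact factors s_ML = (1 − a·Δt)ⁿ − 1 and
s_AP = (1 + b·Δt)ⁿ − 1 over n frames, which the synthetic generator uses as
ground truth. Midline crossings (a hallmark of disorganized mutant
movement) are counted as sign changes of x along a track.

**Polarity.** Cell outlines are reduced to their moment-equivalent ellipse
(exact polygon second moments, not rasterized): orientation θ ∈ [0°, 180°),
aspect ratio √(λ_max/λ_min) ≥ 1, and alignment α = min(θ, 180° − θ) ∈
[0°, 90°] with 0° = perfectly ML-aligned. Protrusion angles are classified
ML/AP by quadrants (or ML/AP/neither by ±30° sectors) and compared by
chi-square; alignment distributions are compared by two-sample
Kolmogorov–Smirnov (K-S) tests; elongation by Mann-Whitney.

**Nuclear signal asymmetry.** DAPI stacks are Otsu-binarized into
26-connected 3D nuclei, volume-filtered, and each nucleus's mean signal
intensity is measured. Nuclei above a background threshold are "positive";
each nucleus gets a normalized position p ∈ [0, 1] along the explant's
principal axis (high-signal end mapped to p < 0.5), and asymmetry is the
two-sample K-S test of p among positives against p among all nuclei.

**Morphometrics.** Explant length is the arc length of an annotated
midline; width is measured perpendicular to the midline at its arc-length
midpoint; neural-plate width/length are landmark distances.

## Worked example

```python
from cextools.synthetic import MIBFieldConfig, simulate_mib_tracks
from cextools.kinematics import summarize_kinematics

cfg = MIBFieldConfig(n_cells=500, conv_rate=0.002, ext_rate=0.002,
                     noise_sigma=0.5, dt=5.0, n_steps=36, seed=1)
tracks, truth = simulate_mib_tracks(cfg)
s = summarize_kinematics(tracks)
print(f"ML slope {s['ml_gradient'].slope:+.4f} (closed form "
      f"{truth.ml_displacement_factor:+.4f}, R2 {s['ml_gradient'].r_squared:.3f})")
print(f"AP slope {s['ap_gradient'].slope:+.4f} (closed form "
      f"{truth.ap_displacement_factor:+.4f})")
print("midline crossings:", s["n_midline_crossings"])
```

prints

```
ML slope -0.3033 (closed form -0.3036, R2 0.997)
AP slope +0.4313 (closed form +0.4308)
midline crossings: 16
```

— a 3-hour, 5-minute-cadence simulation with a·Δt = b·Δt = 0.01: the
fitted convergence slope is negative and the extension slope positive,
both within noise of their exact values; the crossings come from step
noise jittering near-midline cells. The same analyses run on real
`tracks.csv` tables via the CLI:

```sh
cextools simulate --seed 1 --out run/
cextools kinematics --tracks run/tracks.csv --out run/
```

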