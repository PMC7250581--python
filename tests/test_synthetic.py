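"""Tests of the synthetic-data generators: determinism, closed forms,
range invariants, and ground-truth completeness."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import vonmises

from cextools import polarity
from cextools.morphometry import measure_length_width
from cextools.polarity import GeometryError
from cextools.synthetic import (
    MIBFieldConfig,
    PlacementError,
    StabilityError,
    StackConfig,
    simulate_cell_field,
    simulate_explant_shape,
    simulate_mib_tracks,
    simulate_nuclear_stack,
    simulate_pk_cells,
    simulate_protrusions,
)


class TestMIBTracks:
    def test_zero_rates_stationary(self):
        cfg = MIBFieldConfig(
            n_cells=20, conv_rate=0, ext_rate=0, swirl_rate=0, noise_sigma=0, seed=1
        )
        tracks, _ = simulate_mib_tracks(cfg)
        for _, grp in tracks.groupby("track_id"):
            assert np.ptp(grp.x_um) == 0
            assert np.ptp(grp.y_um) == 0

    def test_closed_form_ml_displacement(self, noiseless_mib):
        cfg, tracks, truth = noiseless_mib
        factor = 0.99**36 - 1
        assert truth.ml_displacement_factor == pytest.approx(factor, rel=1e-12)
        for _, grp in tracks.groupby("track_id"):
            x = grp.sort_values("frame").x_um.to_numpy()
            assert (x[-1] - x[0]) == pytest.approx(factor * x[0], rel=1e-9, abs=1e-12)

    def test_swirl_curves_paths_and_crosses_midline(self):
        # w*dt = 0.05 rotates trajectories; cells starting near x=0 cross
        cfg = MIBFieldConfig(
            n_cells=100, conv_rate=0, ext_rate=0, swirl_rate=0.01, noise_sigma=0,
            dt=5.0, n_steps=36, seed=3,
        )
        tracks, _ = simulate_mib_tracks(cfg)
        crossed = 0
        for _, grp in tracks.groupby("track_id"):
            x = grp.sort_values("frame").x_um.to_numpy()
            if np.any(np.sign(x[1:]) != np.sign(x[0])):
                crossed += 1
        assert crossed >= 1

    def test_determinism(self):
        cfg = MIBFieldConfig(n_cells=30, noise_sigma=1.0, seed=42)
        t1, _ = simulate_mib_tracks(cfg)
        t2, _ = simulate_mib_tracks(cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_stability_error(self):
        with pytest.raises(StabilityError):
            MIBFieldConfig(conv_rate=0.5, dt=5.0)

    def test_ground_truth_complete(self, noiseless_mib):
        cfg, tracks, truth = noiseless_mib
        assert len(truth.start_positions) == tracks.track_id.nunique() == cfg.n_cells


class TestCellField:
    def test_uniform_orientations_median_near_45(self):
        outlines, truth = simulate_cell_field(10_000, kappa=0.0, seed=5)
        alphas = np.minimum(truth.table.theta_deg % 180, 180 - truth.table.theta_deg % 180)
        assert np.median(alphas) == pytest.approx(45.0, abs=2.0)
        assert truth.table.theta_deg.between(0, 180, inclusive="left").all()

    def test_concentrated_orientations_small_median(self):
        # Monte-Carlo oracle for the doubled-angle von Mises median
        oracle = np.abs(np.degrees(vonmises(20).rvs(100_000, random_state=0)) / 2)
        outlines, truth = simulate_cell_field(10_000, kappa=20.0, seed=6)
        alphas = np.minimum(truth.table.theta_deg % 180, 180 - truth.table.theta_deg % 180)
        assert np.median(alphas) == pytest.approx(np.median(oracle), abs=0.5)
        assert np.median(alphas) < 10.0

    def test_single_cell_round_trip(self):
        outlines, truth = simulate_cell_field(1, kappa=2.0, seed=7)
        fit = polarity.fit_ellipse(outlines[0])
        diff = abs(fit.theta_deg - truth.table.theta_deg.iloc[0])
        assert min(diff, 180 - diff) < 1.0
        assert fit.aspect_ratio == pytest.approx(truth.table.aspect_ratio.iloc[0], rel=0.01)

    def test_polygons_simple_positive_and_truth_complete(self):
        outlines, truth = simulate_cell_field(50, kappa=1.0, seed=8)
        assert len(outlines) == len(truth.table) == 50
        for o in outlines:
            poly = o.polygon()
            assert poly.is_valid
            assert poly.area > 0

    def test_invalid_aspect_ratio(self):
        with pytest.raises(ValueError):
            simulate_cell_field(5, kappa=1.0, ar_mean=0.8)


class TestProtrusions:
    def test_uniform_ml_fraction_half(self):
        phis = simulate_protrusions(100_000, "uniform", seed=9)
        cats = polarity.classify_protrusions(phis, scheme="quadrant").category
        assert (cats == "ML").mean() == pytest.approx(0.5, abs=0.01)

    def test_bipolar_ml_fraction_matches_von_mises_mass(self):
        # oracle: mass of von Mises(kappa=5) within 45 deg of its center
        mass = vonmises(5).cdf(np.pi / 4) - vonmises(5).cdf(-np.pi / 4)
        phis = simulate_protrusions(100_000, "bipolar_ml", kappa=5.0, seed=10)
        cats = polarity.classify_protrusions(phis, scheme="quadrant").category
        frac = (cats == "ML").mean()
        assert frac == pytest.approx(mass, abs=0.01)
        assert frac > 0.9

    @pytest.mark.parametrize("mode", ["uniform", "bipolar_ml", "anterior_biased"])
    def test_angles_in_range(self, mode):
        phis = simulate_protrusions(1, mode, seed=11)
        assert phis.shape == (1,)
        assert 0 <= phis[0] < 360
        many = simulate_protrusions(5000, mode, seed=12)
        assert np.all((many >= 0) & (many < 360))

    def test_anterior_bias_points_anterior(self):
        phis = simulate_protrusions(50_000, "anterior_biased", kappa=1.0, seed=13)
        # circular mean should sit near +y (90 deg)
        mean_angle = np.degrees(
            np.arctan2(np.mean(np.sin(np.radians(phis))), np.mean(np.cos(np.radians(phis))))
        )
        assert mean_angle == pytest.approx(90.0, abs=3.0)


class TestNuclearStack:
    def test_flat_gradient_no_truth_positives(self):
        cfg = StackConfig(
            shape=(16, 24, 48), n_nuclei=30, signal_gradient_kind="flat",
            gradient_low=80, gradient_high=80, noise_sd=0, amplitude_cv=0.0, seed=14,
        )
        _, _, truth = simulate_nuclear_stack(cfg)
        assert len(truth.nuclei) == 30
        assert truth.nuclei.signal_amplitude.nunique() == 1
        assert not truth.nuclei.positive.any()

    def test_linear_gradient_positives_on_left(self):
        cfg = StackConfig(
            shape=(16, 32, 96), n_nuclei=100, signal_gradient_kind="linear",
            noise_sd=0, seed=15,
        )
        _, _, truth = simulate_nuclear_stack(cfg)
        extent = cfg.shape[2] * cfg.voxel_size[2]
        pos = truth.nuclei[truth.nuclei.positive]
        assert len(pos) > 0
        assert pos.x_um.median() / extent < 0.5

    def test_min_separation_respected(self):
        cfg = StackConfig(shape=(16, 24, 48), n_nuclei=20, seed=16)
        _, _, truth = simulate_nuclear_stack(cfg)
        pts = truth.nuclei[["z_um", "y_um", "x_um"]].to_numpy()
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= cfg.min_separation

    def test_placement_error_when_overfull(self):
        with pytest.raises(PlacementError):
            cfg = StackConfig(shape=(10, 10, 10), n_nuclei=500, seed=17,
                              max_placement_tries=2000)
            simulate_nuclear_stack(cfg)

    def test_determinism(self):
        cfg = StackConfig(shape=(12, 16, 32), n_nuclei=10, seed=18)
        d1, s1, _ = simulate_nuclear_stack(cfg)
        d2, s2, _ = simulate_nuclear_stack(cfg)
        assert np.array_equal(d1, d2)
        assert np.array_equal(s1, s2)


class TestPkCells:
    def test_all_anterior(self):
        outlines, puncta, truth = simulate_pk_cells(30, 1.0, 0.0, seed=19)
        scores = polarity.score_pk_cells(outlines, puncta)
        assert (scores.category == "anterior").all()

    def test_all_none(self):
        outlines, puncta, truth = simulate_pk_cells(30, 0.0, 0.0, seed=20)
        scores = polarity.score_pk_cells(outlines, puncta)
        assert (scores.category == "none").all()
        assert not puncta

    def test_category_proportions_recovered(self):
        outlines, puncta, truth = simulate_pk_cells(10_000, 0.5, 0.3, seed=21)
        scores = polarity.score_pk_cells(outlines, puncta)
        fracs = scores.category.value_counts(normalize=True)
        assert fracs["anterior"] == pytest.approx(0.5, abs=0.02)
        assert fracs["membrane_other"] == pytest.approx(0.3, abs=0.02)
        assert fracs["none"] == pytest.approx(0.2, abs=0.02)
        # scored categories agree with ground truth per cell
        merged = scores.merge(truth.table, on="cell_id", suffixes=("_scored", "_true"))
        assert (merged.category_scored == merged.category_true).mean() > 0.99

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            simulate_pk_cells(5, 0.8, 0.5)


class TestExplantShape:
    def test_straight_ratio(self):
        shape = simulate_explant_shape(10.0, 2.0, curvature=0.0)
        m = measure_length_width(shape)
        assert m.ratio == pytest.approx(5.0, rel=1e-3)

    def test_arc_preserves_ratio(self):
        shape = simulate_explant_shape(10.0, 2.0, curvature=0.05)
        m = measure_length_width(shape)
        assert m.length_um == pytest.approx(10.0, rel=0.01)
        assert m.ratio == pytest.approx(5.0, rel=0.02)

    def test_invalid_width(self):
        with pytest.raises(GeometryError):
            simulate_explant_shape(10.0, 0.0)

    def test_degenerate_arc(self):
        with pytest.raises(GeometryError):
            simulate_explant_shape(100.0, 2.0, curvature=0.05)
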