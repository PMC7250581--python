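"""3D nuclear segmentation, signal measurement, positivity calling and
axis asymmetry, validated against the stack generator's ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from cextools.nuclear_signal import (
    analyze_explant,
    asymmetry_test,
    call_positive,
    measure_nuclear_signal,
    orient_and_position,
    segment_nuclei_3d,
)
from cextools.synthetic import StackConfig, simulate_nuclear_stack

SPARSE = dict(
    shape=(20, 40, 80), n_nuclei=10, min_separation=14.0, noise_sd=0.0,
    amplitude_cv=0.0,
)


@pytest.fixture(scope="module")
def sparse_stack():
    cfg = StackConfig(**SPARSE, signal_gradient_kind="linear", seed=40)
    dapi, signal, truth = simulate_nuclear_stack(cfg)
    return cfg, dapi, signal, truth


class TestSegmentation:
    def test_noiseless_blobs_counted_and_located(self, sparse_stack):
        cfg, dapi, signal, truth = sparse_stack
        nuclei, labels = segment_nuclei_3d(dapi, cfg.voxel_size)
        assert len(nuclei) == cfg.n_nuclei
        got = nuclei[["x_um", "y_um", "z_um"]].to_numpy()
        want = truth.nuclei[["x_um", "y_um", "z_um"]].to_numpy()
        d = np.linalg.norm(got[:, None] - want[None, :], axis=2)
        # each centroid within one voxel of exactly one true nucleus
        assert (d.min(axis=1) < max(cfg.voxel_size)).all()
        assert len(set(d.argmin(axis=1))) == cfg.n_nuclei

    def test_all_zero_stack_empty(self):
        with pytest.warns(UserWarning):
            nuclei, labels = segment_nuclei_3d(np.zeros((8, 8, 8)), (1, 1, 1))
        assert nuclei.empty

    def test_volume_filter_removes_small_blob(self, sparse_stack):
        cfg, dapi, signal, truth = sparse_stack
        nuclei, _ = segment_nuclei_3d(dapi, cfg.voxel_size, vmin_um3=1e5)
        assert nuclei.empty

    def test_absolute_threshold(self, sparse_stack):
        cfg, dapi, _, _ = sparse_stack
        nuclei, _ = segment_nuclei_3d(
            dapi, cfg.voxel_size, threshold_method="absolute",
            absolute_threshold=cfg.dapi_amplitude / 2,
        )
        assert len(nuclei) == cfg.n_nuclei


class TestMeasurement:
    def test_uniform_signal(self, sparse_stack):
        cfg, dapi, _, _ = sparse_stack
        nuclei, labels = segment_nuclei_3d(dapi, cfg.voxel_size)
        out = measure_nuclear_signal(nuclei, labels, np.full(dapi.shape, 7.0))
        assert np.allclose(out.mean_signal, 7.0)

    def test_signal_equals_dapi(self, sparse_stack):
        cfg, dapi, _, _ = sparse_stack
        nuclei, labels = segment_nuclei_3d(dapi, cfg.voxel_size)
        out = measure_nuclear_signal(nuclei, labels, dapi)
        assert np.allclose(out.mean_signal, out.mean_dapi)

    def test_gradient_rank_correlation(self, sparse_stack):
        cfg, dapi, signal, truth = sparse_stack
        nuclei, labels = segment_nuclei_3d(dapi, cfg.voxel_size)
        out = measure_nuclear_signal(nuclei, labels, signal)
        # match to truth by position, then mean signal must track amplitude
        got = out[["x_um", "y_um", "z_um"]].to_numpy()
        want = truth.nuclei[["x_um", "y_um", "z_um"]].to_numpy()
        idx = np.linalg.norm(got[:, None] - want[None, :], axis=2).argmin(axis=1)
        rho = spearmanr(out.mean_signal, truth.nuclei.signal_amplitude.iloc[idx]).statistic
        assert rho > 0.9

    def test_shape_mismatch(self, sparse_stack):
        cfg, dapi, _, _ = sparse_stack
        nuclei, labels = segment_nuclei_3d(dapi, cfg.voxel_size)
        with pytest.raises(ValueError):
            measure_nuclear_signal(nuclei, labels, np.zeros((2, 2, 2)))


class TestPositivity:
    def table(self, vals):
        return pd.DataFrame({"mean_signal": vals})

    def test_absolute(self):
        out, thr = call_positive(self.table([1, 1, 1, 10]), "absolute", threshold=5)
        assert out.positive.sum() == 1 and thr == 5

    def test_control_percentile_on_itself(self, rng):
        vals = rng.normal(100, 10, 4000)
        out, thr = call_positive(self.table(vals), "control_percentile", control=vals)
        assert out.positive.mean() == pytest.approx(0.025, abs=0.005)

    def test_truth_recovered_at_generator_level(self, sparse_stack):
        cfg, dapi, signal, truth = sparse_stack
        nuclei, labels = segment_nuclei_3d(dapi, cfg.voxel_size)
        out = measure_nuclear_signal(nuclei, labels, signal)
        got = out[["x_um", "y_um", "z_um"]].to_numpy()
        want = truth.nuclei[["x_um", "y_um", "z_um"]].to_numpy()
        idx = np.linalg.norm(got[:, None] - want[None, :], axis=2).argmin(axis=1)
        # the measured mean is the amplitude attenuated by the mask average;
        # scale the generator's positivity level by the same attenuation,
        # estimated from the brightest nucleus
        atten = out.mean_signal.max() / truth.nuclei.signal_amplitude.iloc[idx].max()
        out2, _ = call_positive(
            out, "absolute", threshold=truth.positive_level * atten
        )
        assert list(out2.positive) == list(truth.nuclei.positive.iloc[idx])

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            call_positive(self.table([1.0]), "control_percentile")


class TestOrientation:
    def nuclei_at(self, xs, signal):
        return pd.DataFrame(
            {"x_um": xs, "y_um": np.zeros(len(xs)), "mean_signal": signal,
             "positive": [False] * len(xs)}
        )

    def test_equal_signal_unoriented(self):
        out, flipped, unoriented = orient_and_position(self.nuclei_at([0, 5, 10], [2, 2, 2]))
        assert list(out.axis_position) == [0.0, 0.5, 1.0]
        assert unoriented and not flipped

    def test_high_signal_flips_to_low_p(self):
        out, flipped, unoriented = orient_and_position(self.nuclei_at([0, 5, 10], [1, 1, 5]))
        assert list(out.axis_position) == [1.0, 0.5, 0.0]
        assert flipped and not unoriented

    def test_rotation_invariance_of_p(self, rng):
        pts = np.stack([rng.uniform(0, 100, 40), rng.normal(0, 5, 40)], axis=1)
        sig = rng.uniform(1, 2, 40)
        df = pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1],
                           "mean_signal": sig, "positive": False})
        t = np.radians(35)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        moved = pts @ rot.T
        df2 = df.assign(x_um=moved[:, 0], y_um=moved[:, 1])
        p1 = orient_and_position(df)[0].axis_position.to_numpy()
        p2 = orient_and_position(df2)[0].axis_position.to_numpy()
        assert np.allclose(p1, p2, atol=1e-9) or np.allclose(p1, 1 - p2, atol=1e-9)

    def test_coincident_centroids_rejected(self):
        with pytest.raises(ValueError):
            orient_and_position(self.nuclei_at([1, 1, 1], [1, 1, 1]))


class TestAsymmetry:
    def test_positives_equal_all_gives_zero_d(self):
        df = pd.DataFrame({"axis_position": np.linspace(0, 1, 20), "positive": True})
        res = asymmetry_test(df)
        assert res.ks_D == 0
        assert res.n_positive == res.n_total == 20

    def test_zero_positives_reported_without_test(self):
        df = pd.DataFrame({"axis_position": np.linspace(0, 1, 5), "positive": False})
        with pytest.warns(UserWarning):
            res = asymmetry_test(df)
        assert res.ks_p is None and res.n_positive == 0

    def test_left_concentrated_positives_detected(self, rng):
        p = rng.uniform(0, 1, 200)
        df = pd.DataFrame({"axis_position": p, "positive": p < 0.2})
        res = asymmetry_test(df)
        assert res.ks_p < 0.01
        assert res.median_p_positive < 0.5


class TestEndToEnd:
    def test_gradient_explant_asymmetric(self):
        # sigmoid profile: signal high on the left half, background on the
        # right, so positives are a left-concentrated minority of all nuclei
        cfg = StackConfig(signal_gradient_kind="sigmoid", seed=50)
        dapi, signal, _ = simulate_nuclear_stack(cfg)
        ctrl_cfg = StackConfig(signal_gradient_kind="flat", seed=51)
        cd, cs, _ = simulate_nuclear_stack(ctrl_cfg)
        ctrl_nuclei, _ = analyze_explant(cd, cs, cfg.voxel_size, strategy="robust_z")
        nuclei, res = analyze_explant(
            dapi, signal, cfg.voxel_size,
            control_signals=ctrl_nuclei.mean_signal.to_numpy(),
        )
        assert res.n_positive > 10
        assert res.ks_p < 1e-4
        assert res.median_p_positive < 0.5

    def test_flat_explant_usually_symmetric(self):
        cfg = StackConfig(signal_gradient_kind="flat", seed=52)
        dapi, signal, _ = simulate_nuclear_stack(cfg)
        nuclei, res = analyze_explant(dapi, signal, cfg.voxel_size, strategy="robust_z")
        assert res.n_total > 100
        # no built-in asymmetry: median of positives has no systematic side
        assert res.ks_D is not None
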