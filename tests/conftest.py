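import numpy as np
import pytest

from cextools.synthetic import MIBFieldConfig, simulate_mib_tracks


@pytest.fixture
def noiseless_mib():
    """Deterministic convergence+extension simulation (a*dt = b*dt = 0.01)."""
    cfg = MIBFieldConfig(
        n_cells=50, conv_rate=0.002, ext_rate=0.002, swirl_rate=0.0,
        noise_sigma=0.0, dt=5.0, n_steps=36, seed=7,
    )
    tracks, truth = simulate_mib_tracks(cfg)
    return cfg, tracks, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
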