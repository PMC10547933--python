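import numpy as np
import pytest

from survsync.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small two-colony dataset with known latent truth."""
    cfg = SimulationConfig(n_occasions=12, entry_totals=(300, 150),
                           transient_fraction=0.2, seed=42)
    data, truth = simulate_dataset(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def tiny_sim():
    """Transient-free dataset small enough for quick MCMC smoke fits."""
    cfg = SimulationConfig(n_occasions=8, entry_totals=(150, 120),
                           transient_fraction=0.0, sigma_gamma=0.5,
                           sigma_phi_eps=0.3, sigma_p_eps=0.3,
                           delta_seen=(0.5, 0.6), delta_unseen=(0.35, 0.4),
                           alpha=(0.9, 0.88), seed=7)
    data, truth = simulate_dataset(cfg)
    return cfg, data, truth


@pytest.fixture
def rng():
    return np.random.default_rng(123)
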