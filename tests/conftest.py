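import numpy as np
import pytest

from tspecies import SimulationConfig, simulate_ks_values, train_variance_model


@pytest.fixture(scope="session")
def model_1e8():
    """Variance->Ne model trained at mu=1e-8 on the full study grid."""
    return train_variance_model(1e-8, seed=42)


@pytest.fixture(scope="session")
def store_1e8(model_1e8):
    return {model_1e8.mu: model_1e8}


@pytest.fixture(scope="session")
def ks_ne5e4():
    """Simulated Ks distribution at Ne=5e4, T=1e6, mu=1e-8 (study conditions)."""
    cfg = SimulationConfig(ne=5e4, mu=1e-8, t_div=1e6, seed=1234)
    return simulate_ks_values(cfg)
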