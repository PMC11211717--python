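import numpy as np
import pytest

from wmdrift.model import ModelParams
from wmdrift.pso import PSOConfig


@pytest.fixture(scope="session")
def scaled_pso() -> PSOConfig:
    """Scaled-down swarm used throughout the suite (reference is 100x1000)."""
    return PSOConfig(n_particles=30, max_iter=300, patience=60, n_restarts=2)


@pytest.fixture(scope="session")
def representative() -> ModelParams:
    """Representative across-subject generating values for the full model."""
    return ModelParams(
        sigma_mem=4.2856,
        delta_thresh=11.1370,
        theta=0.0203,
        lam=0.0049,
        sigma_dec=3.0802,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
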