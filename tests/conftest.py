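import numpy as np
import pytest

from cdpreform import SimulationConfig


@pytest.fixture
def noise_free():
    """Simulation config with no measurement noise (deterministic path)."""
    return SimulationConfig(seed=0, noise_cv=0.0, replicates=1)


@pytest.fixture
def assay_noise():
    """Realistic assay noise: 2% CV, triplicate measurements."""
    return SimulationConfig(seed=42, noise_cv=0.02, replicates=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
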