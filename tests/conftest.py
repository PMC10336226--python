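import numpy as np
import pytest

from ftsts import (ConnectivitySpec, ModelParams, STDPParams,
                   SimulationConfig, SeizureInput)


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def small_connectivity():
    """A 20+20 network with broad kernels (fast, no row underflow)."""
    return ConnectivitySpec(N_E=20, N_I=20, sigma_E=0.1, sigma_I=0.12,
                            W0_EE=104.0, W0_EI=100.0, W0_II=250.0,
                            W0_IE=250.0, W_UI=50.0)


@pytest.fixture
def small_config(small_connectivity):
    """A short, cheap simulation config on the small network."""
    return SimulationConfig(
        duration=2000.0, seed=7, connectivity=small_connectivity,
        seizure=SeizureInput(amplitude=200.0, start=500.0, duration=500.0,
                             targets=(8, 12)),
        record_dt=100.0)
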