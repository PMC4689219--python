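import numpy as np
import pytest
from hypothesis import settings

from fateswitch import (DoseDistribution, ModelParameters, NoiseModel,
                        PulseProtocol, generate_timelapse)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    """Default calibrated circuit parameters (bistable at s=1)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def protocol():
    return PulseProtocol()


@pytest.fixture(scope="session")
def dose_dist():
    return DoseDistribution()


@pytest.fixture(scope="session")
def symmetric_params():
    """Mirror-symmetric toggle (identical rates, no signaling input)."""
    return ModelParameters(alpha_N=1.0, alpha_G=1.0, K_GN=0.3, K_NG=0.3,
                           h_N=4.0, h_G=4.0, gamma_N=0.5, gamma_G=0.5,
                           mode="none")


@pytest.fixture(scope="session")
def small_timelapse(params, protocol, dose_dist):
    """A modest noisy time-lapse dataset shared across analysis tests
    (60 cells, hourly frames)."""
    return generate_timelapse(params, protocol, dose_dist, n=60,
                              noise=NoiseModel(), frame_interval=1.0,
                              seed=1234)
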