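import numpy as np
import pytest
from hypothesis import settings

from semgfat.synthetic_semg import SimConfig, generate_recording

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rec60():
    """One deterministic 40-cycle session at 60 deg/s."""
    return generate_recording(SimConfig(speed=60, seed=3), "S000")


@pytest.fixture(scope="session")
def rec180():
    """One deterministic 40-cycle session at 180 deg/s."""
    return generate_recording(SimConfig(speed=180, seed=3), "S000")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
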