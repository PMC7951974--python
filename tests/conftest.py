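import numpy as np
import pytest

from s2spike.network import S2SConfig
from s2spike.sim import SimConfig, benchmark_recordings


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_net_config():
    """A small but structurally complete network for fast unit tests."""
    return S2SConfig(w_seq=20, nFilt_in=6, n_hidden=2, nhu=5, seed=42)


@pytest.fixture(scope="session")
def tiny_recordings():
    """Six short synthetic neurons for fast training-path tests."""
    cfg = SimConfig(duration_s=20.0, rate_hz=1.5, seed=77)
    return benchmark_recordings(6, cfg)
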