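import numpy as np
import pytest

import adloop as al


@pytest.fixture(scope="session")
def small_con():
    """10-region modular synthetic connectome (fast closed-loop fixture)."""
    return al.synthetic_connectome(5, "modular", rng_seed=7)


@pytest.fixture(scope="session")
def path_con():
    """12-region path-topology connectome for wavefront checks."""
    return al.synthetic_connectome(6, "path", rng_seed=3)


@pytest.fixture(scope="session")
def cingulum_con():
    """40-region synthetic connectome with the bundled annotation."""
    return al.synthetic_connectome(20, "modular", rng_seed=1)


@pytest.fixture
def fast_config():
    """Scaled-down closed-loop schedule for unit tests."""
    return al.ClosedLoopConfig(years=3.0, bnm_duration_ms=3000.0,
                               bnm_discard_ms=1000.0, rng_seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
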