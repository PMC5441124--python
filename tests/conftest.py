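import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bsentropy as b

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: The hand-worked six-beat series: vectors (800,820,810) -> mode 54,
#: (820,810,800) -> 27, (810,800,820) -> 45, (800,820,810) -> 54 again.
WORKED_SERIES = [800.0, 820.0, 810.0, 800.0, 820.0, 810.0]


@pytest.fixture
def params():
    return b.BseParams(m=3, alpha=0.5, window=300)


@pytest.fixture(scope="session")
def ar1_series():
    return b.ar1_intervals(2000, seed=7)


@pytest.fixture(scope="session")
def random_walk_series():
    return b.random_walk_intervals(5000, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
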