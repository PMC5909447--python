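import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stopscan as ss

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table11():
    return ss.TABLE_11


@pytest.fixture(scope="session")
def table4():
    return ss.TABLE_4


@pytest.fixture(scope="session")
def small_genome():
    """A deterministic mid-GC genome used across module tests."""
    rng = np.random.default_rng(12345)
    return ss.generate_genome(
        "fixture", rng, n_cds=40, cds_length=(60, 160), gc3_target=0.45
    )


@pytest.fixture(scope="session")
def at_rich_genome():
    rng = np.random.default_rng(54321)
    return ss.generate_genome(
        "fixture_at", rng, n_cds=40, cds_length=(60, 160), gc3_target=0.22
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
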