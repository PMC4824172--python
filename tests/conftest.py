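import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dupsel

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixtures():
    return dupsel.make_fixtures()


@pytest.fixture(scope="session")
def gene_tree(fixtures):
    return fixtures["gene_tree"]


@pytest.fixture(scope="session")
def species_tree(fixtures):
    return fixtures["species_tree"]


@pytest.fixture(scope="session")
def uniform_pi():
    return np.full(61, 1.0 / 61)
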