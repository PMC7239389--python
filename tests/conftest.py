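import numpy as np
import pytest

from nichebias import Domain, EnvField, make_env_grid


@pytest.fixture(scope="session")
def grid():
    """Default environmental grid: 2001 nodes on [-5, 5], uniform mu_x."""
    return make_env_grid(Domain(), EnvField(), 2001)


@pytest.fixture(scope="session")
def coarse_grid():
    return make_env_grid(Domain(), EnvField(), 501)


@pytest.fixture(scope="session")
def domain():
    return Domain()


@pytest.fixture(scope="session")
def field():
    return EnvField()
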