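import numpy as np
import pytest

from ringdrift.environment import EnvironmentalPrior, make_experiment_session
from ringdrift.ring import make_grid


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def prior4():
    """The four-peak smooth environmental prior used throughout."""
    return EnvironmentalPrior(form="exp_cosine", amplitude=1.0, modes=4)


@pytest.fixture(scope="session")
def small_session():
    """A 10-short / 10-long trial session for cheap pipeline tests."""
    return make_experiment_session(0.3, n_short=10, n_long=10, seed=42)
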