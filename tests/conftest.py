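import numpy as np
import pytest

from explearn import ScoreModel, build_grid
from explearn.fitting import DMCurveLibrary


@pytest.fixture(scope="session")
def score_model():
    """Shared default-grid score model (tables are read-only)."""
    return ScoreModel()


@pytest.fixture(scope="session")
def tiny_model():
    """3 x 3 grid model used for brute-force oracle comparisons."""
    return ScoreModel(build_grid(step=1.0))


@pytest.fixture(scope="session")
def dm_library(score_model):
    """Shared Gamma/tau0 curve library at the standard 24 x 100 scale.

    Built lazily: entries are simulated only for the Gamma values a test
    touches, and cached for every later test in the session.
    """
    return DMCurveLibrary(seed=11, model=score_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
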