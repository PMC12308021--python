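import numpy as np
import pytest

from numtune.design import build_timeline
from numtune.prf import GridPredictions


@pytest.fixture(scope="session")
def timeline():
    """Default single-run stimulus timeline (4 cycles, 432 events)."""
    return build_timeline()


@pytest.fixture(scope="session")
def grid_predictions(timeline):
    """Predicted BOLD signals for the full default parameter grid,
    shared across tests (construction is cheap but not free)."""
    return GridPredictions(timeline)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
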