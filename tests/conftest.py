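import numpy as np
import pytest

from krtecon import clusters
from krtecon.panel import PanelConfig, generate_panel


@pytest.fixture(scope="session")
def default_panel():
    """One default synthetic 14-country x 2-year panel (seeded)."""
    return generate_panel(PanelConfig(seed=0))


@pytest.fixture(scope="session")
def default_config():
    return PanelConfig(seed=0)


@pytest.fixture()
def transition_fixture():
    """The worked-example 3x3 transition matrix with row totals (4, 6, 4)."""
    counts = np.array([[2, 2, 0], [0, 3, 3], [0, 2, 2]])
    return clusters.TransitionMatrix(counts=counts)
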