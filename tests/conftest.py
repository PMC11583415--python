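import numpy as np
import pytest

from ginet.simulate import default_screen_config, simulate_dependency_panel
from ginet.studies import planted_term_collection  # noqa: F401  (re-export for tests)


@pytest.fixture(scope="session")
def screen_panel():
    """One default study-condition panel (200 lines x 2000 genes, planted
    co-essential pair G0002~G0003 at rho 0.9, planted SL G0001->G0010)."""
    return simulate_dependency_panel(default_screen_config(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
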