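import numpy as np
import pytest

from chipregulon.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One seeded default study shared by read-only tests."""
    return simulate_study(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
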