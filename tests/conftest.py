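import numpy as np
import pandas as pd
import pytest

from ds21 import SimConfig, simulate_overexpression_study


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def study(default_config):
    """One default-size simulated overexpression study shared across tests."""
    return simulate_overexpression_study(default_config)


@pytest.fixture(scope="session")
def small_study():
    """A fast, smaller study for tests that re-run the DE stage often."""
    cfg = SimConfig(seed=7, n_probesets=500)
    return cfg, simulate_overexpression_study(cfg)


@pytest.fixture
def toy_matrix_df() -> pd.DataFrame:
    rng = np.random.default_rng(3)
    return pd.DataFrame(
        rng.normal(8.0, 1.0, size=(5, 4)),
        index=[f"P{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(4)],
    )
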