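import numpy as np
import pandas as pd
import pytest

from domlink import synthetic_data as sd


@pytest.fixture(scope="session")
def small_universe():
    """A 30-formula universe shared by tests that need valid formulas."""
    cfg = sd.SimulationConfig(seed=11, n_true_formulas=30)
    return sd.generate_formula_universe(cfg)


@pytest.fixture(scope="session")
def default_universe():
    """The 200-formula default universe (generated once per session)."""
    cfg = sd.SimulationConfig(seed=1)
    return sd.generate_formula_universe(cfg)


@pytest.fixture()
def sample_frame():
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.uniform(0.1, 1.0, size=(8, 5)),
        index=[f"S{i}" for i in range(8)],
        columns=[f"f{i}" for i in range(5)],
    )
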