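import warnings

import numpy as np
import pytest

import wintrack as wt

# mixed-model convergence chatter is irrelevant to the assertions
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_scenario():
    """One compact synthetic study shared by read-only tests."""
    cfg = wt.ScenarioConfig(seed=42, n_animals=3, n_days=3)
    return wt.generate_scenario(cfg, with_ski=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
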