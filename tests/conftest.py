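import numpy as np
import pytest

from empoweranc import synthdata as sd
from empoweranc.simstudy import toy_cohort


@pytest.fixture(scope="session")
def toy():
    return toy_cohort()


@pytest.fixture(scope="session")
def small_config():
    return sd.DGPConfig(n_mothers=800, n_villages=40, seed=123)


@pytest.fixture(scope="session")
def cohort2000():
    """One medium cohort shared across read-only tests."""
    cfg = sd.DGPConfig(n_mothers=2000, n_villages=80, seed=42)
    return sd.generate_cohort(cfg, truth_draws=None)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
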