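import numpy as np
import pytest

from prognet import CohortConfig, simulate_cohorts


@pytest.fixture(scope="session")
def study():
    """One small synthetic study bundle shared across tests."""
    cfg = CohortConfig(
        n_samples=200,
        n_tfs=5,
        n_targets=50,
        regulon_size_range=(5, 15),
        noise_sd=0.2,
        n_signature=20,
        seed=11,
    )
    return cfg, simulate_cohorts(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
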