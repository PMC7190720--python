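import numpy as np
import pytest

from grapekin import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def clean_study():
    """Error-free founder-star study, small locus count for unit tests."""
    cfg = SimulationConfig(
        n_founders=10, snp_loci=1500, error_rate=0.0, missing_rate=0.0, seed=11
    )
    study, truth = simulate_study(cfg)
    return study, truth


@pytest.fixture(scope="session")
def noisy_study():
    """Founder-star study with realistic array noise."""
    cfg = SimulationConfig(
        n_founders=10, snp_loci=1500, error_rate=0.002, missing_rate=0.02, seed=13
    )
    study, truth = simulate_study(cfg)
    return study, truth


@pytest.fixture
def rng():
    return np.random.default_rng(202)
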