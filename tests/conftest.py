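import numpy as np
import pytest
from hypothesis import settings

from connid import SyntheticConfig, generate_cohort

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coupled_cohort():
    """13 dyads, 50 ROIs, strong planted coupling and low noise.

    In this regime every CBI sub-model should identify all couples while the
    whole-brain fingerprint stays at chance (no dyad-shared component spans
    the full connectome).
    """
    cfg = SyntheticConfig(n_dyads=13, r=50, T=150, coupling=1.5, noise_sd=0.1, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """13 dyads, 50 ROIs, no coupling at all: pure noise around the baseline."""
    cfg = SyntheticConfig(
        n_dyads=13, r=50, T=150, coupling=0.0, noise_sd=0.3, seed=12
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort (6 dyads, 10 ROIs) for oracle comparisons."""
    cfg = SyntheticConfig(n_dyads=6, r=10, T=40, coupling=0.8, noise_sd=0.3, seed=13)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_spd(rng, r, scale=1.0):
    a = rng.standard_normal((r, r))
    return scale * (a @ a.T) + r * np.eye(r)
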