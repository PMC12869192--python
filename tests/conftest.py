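import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

from homecage.simulate import SimConfig, simulate_session  # noqa: E402


@pytest.fixture(scope="session")
def small_session():
    """A short noisy 3-mouse session shared across tests."""
    cfg = SimConfig(n_mice=3, duration_s=120.0, seed=7)
    return cfg, simulate_session(cfg)


@pytest.fixture(scope="session")
def clean_session():
    """Noiseless, never-occluded 2-mouse session."""
    cfg = SimConfig(
        n_mice=2, duration_s=120.0, seed=3,
        miss_prob=0.0, jitter_px_sd=0.0, bundle_dist_cm=0.0, exclusion_cm=0.0,
    )
    return cfg, simulate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
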