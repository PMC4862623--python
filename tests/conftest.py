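import numpy as np
import pytest

from eegfp import CVConfig, SimSpec
from eegfp.simulate import simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_study():
    """One 120-s planted session pool (2 positives), reused read-only."""
    spec = SimSpec(n_sessions=2, n_positive=2, duration_s=300.0, seed=42,
                   snr=10.0)
    sessions, truths = simulate_study(spec)
    return spec, sessions, truths


@pytest.fixture(scope="session")
def noiseless_study():
    """Three identical-coefficient sessions with an infinite SNR target."""
    spec = SimSpec(n_sessions=3, n_positive=3, duration_s=300.0, seed=7,
                   snr=np.inf)
    sessions, truths = simulate_study(spec)
    return spec, sessions, truths


@pytest.fixture
def fast_cv():
    return CVConfig(n_inner_splits=8, lambda_grid=np.logspace(-2, 4, 7),
                    seed=11)
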