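import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_session():
    """Short noise-free simulated session with ground truth (shared)."""
    from matmotion.simulator import NoiseParams, simulate_session, standard_script

    script = standard_script(duration=12.0, n_reaches=6, seed=7)
    return simulate_session(script=script, noise=NoiseParams.zero(), seed=7)


@pytest.fixture(scope="session")
def noisy_session():
    """Short noisy simulated session with ground truth (shared)."""
    from matmotion.simulator import simulate_session, standard_script

    script = standard_script(duration=12.0, n_reaches=6, seed=3)
    return simulate_session(script=script, seed=3)


@pytest.fixture(scope="session")
def processed_noisy(noisy_session):
    """Pipeline output on the shared noisy session."""
    from matmotion.config import Config
    from matmotion.pipeline import process_session

    bundle, truth = noisy_session
    return process_session(bundle, Config()), truth
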