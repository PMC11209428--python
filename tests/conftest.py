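import numpy as np
import pytest

from mrcpkit.synth import SessionConfig, generate_session


@pytest.fixture(scope="session")
def default_session():
    """One full session under study-default conditions (100 movements)."""
    return generate_session(SessionConfig(seed=1))


@pytest.fixture(scope="session")
def small_session():
    """A short session (20 movements) for stage-level tests."""
    return generate_session(SessionConfig(seed=3, n_movements=20))


@pytest.fixture(scope="session")
def quiet_session():
    """Noise-free session: MRCP trains only, no oscillations or blinks."""
    cfg = SessionConfig(seed=2, n_movements=20, noise_sd=0.0,
                        alpha_amp=0.0, beta_amp=0.0, artifact_rate=0.0)
    return generate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
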