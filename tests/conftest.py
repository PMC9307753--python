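import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import neurovoc as nv

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_session():
    """60 s planted-coupling session, scaled down for unit tests."""
    return nv.synth_session(n_words=20, n_channels=6, audio_rate=16000.0, seed=7)


@pytest.fixture(scope="session")
def small_fit(small_session):
    """Decoder model + cross-validated results on the small session."""
    model = nv.SpectrogramDecoder.from_session(small_session)
    return model, model.fit()


@pytest.fixture(scope="session")
def uncoupled_session():
    """60 s session without planted coupling (modulation_depth 0)."""
    return nv.synth_session(
        n_words=20, n_channels=6, audio_rate=16000.0, modulation_depth=0.0, seed=13
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
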