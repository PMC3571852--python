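import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def network():
    from drowsefuse.fbn import default_network

    return default_network()


@pytest.fixture(scope="session")
def short_session():
    """A 60 s half-awake/half-drowsy session shared across tests."""
    from drowsefuse.synth import SessionSpec, synth_session

    return synth_session(SessionSpec(duration=60.0, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
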