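import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from oddball_mismatch.sequence_design import make_tone_set


@pytest.fixture(scope="session")
def tones():
    return make_tone_set(1000.0, 0.5, 10, 60.0)


@pytest.fixture(scope="session")
def mpfc_session():
    """One default mPFC synthetic session, shared across tests."""
    from oddball_mismatch.synthetic_session import SessionConfig, simulate_session

    return simulate_session(SessionConfig(seed=11))
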