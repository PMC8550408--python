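import numpy as np
import pytest

from blockreg import (
    DEFAULT_PROFILES,
    ProtocolConfig,
    Setup,
    build_protocol,
    simulate_subject,
)


@pytest.fixture(scope="session")
def protocol():
    return build_protocol(ProtocolConfig(seed=0))


@pytest.fixture(scope="session")
def desktop_session(protocol):
    """One simulated 2D Desktop session (with 10 Hz samples)."""
    return simulate_subject(
        DEFAULT_PROFILES[Setup.DESKTOP_2D], protocol, subject_id="s000", seed=42
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
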