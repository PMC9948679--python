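import numpy as np
import pytest

from reflexloop.session import ProtocolConfig
from reflexloop.signal_core import SignalConfig
from reflexloop.simulator import VirtualParticipant


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def signal_config():
    return SignalConfig(sample_rate=2000.0)


@pytest.fixture
def protocol_config():
    return ProtocolConfig()


@pytest.fixture
def quiet_participant():
    """Noise-free virtual participant: every source of variability off."""
    return VirtualParticipant(
        background_drive=0.0,
        antagonist_drive=0.0,
        drive_noise=0.0,
        response_noise=0.0,
    )
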