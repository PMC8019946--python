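import numpy as np
import pytest

from envtrack.containers import EegRecording, make_event_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_recording(rng):
    """30 s of 4-channel white-noise EEG with two events."""
    data = rng.standard_normal((4, 15000)) * 20
    events = make_event_table([5.0, 20.0], ["name", "control"], 500.0)
    return EegRecording(data, 500.0, ["Fz", "Cz", "Pz", "Oz"], events=events)
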