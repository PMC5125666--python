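import numpy as np
import pytest

import fest

# Audio tests run at a reduced rate (still above twice the 5.5 kHz upper
# band edge) to keep filtering fast.
AUDIO_RATE = 16000


@pytest.fixture(scope="session")
def battery():
    return fest.load_battery()


@pytest.fixture(scope="session")
def fixture_clips(battery):
    return fest.make_fixture_audio(battery, rate=AUDIO_RATE, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def perfect_session(battery, listener_id="p1", group="YNH"):
    """A session answering every trial exactly right."""
    trials = [
        fest.TrialResponse(
            sequence_name=q.name,
            rating=0.9 if q.coherence == "coherent" else 0.1,
            chosen=q.labels,
            rating_time=2.0,
            identification_time=30.0,
        )
        for q in battery.sequences
    ]
    return fest.SessionResult(listener_id=listener_id, group=group, trials=trials)
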