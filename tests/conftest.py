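import numpy as np
import pytest

from routineform.events import EVENT_KINDS, EventStream


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_stream(rng, n_events=50, duration=600.0, subject_id="s0"):
    """A random but valid event stream on the 10 ms grid."""
    times = np.sort(rng.integers(0, int(duration * 100), size=n_events)) / 100.0
    # enforce strictly increasing on the grid to avoid zero-duration ties
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            times[i] = times[i - 1] + 0.01
    kinds = rng.choice(EVENT_KINDS, size=n_events)
    return EventStream(subject_id=subject_id, times=np.round(times, 2),
                       kinds=kinds, session_duration=max(duration, times[-1]),
                       resolution=0.01)
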