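import numpy as np
import pytest

from erpsig import ContinuousRecording, EpochSet, EventTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_recording(rng):
    """10-s, 100-Hz, 4-channel recording with events every second."""
    data = rng.normal(0.0, 1.0, size=(4, 1000))
    rec = ContinuousRecording(
        data, 100.0, ["Fz", "Cz", "Pz", "Oz"], subject_id="sub-toy"
    )
    events = EventTable(np.arange(100, 900, 100), ["go", "nogo"] * 4)
    return rec, events


def make_epochs(data, srate=100.0, condition="A", t0=0.0, **kw):
    """EpochSet from a (channels, times, trials) array with times starting t0."""
    data = np.asarray(data, dtype=float)
    times = t0 + np.arange(data.shape[1]) / srate
    return EpochSet(data=data, times=times, srate=srate, condition=condition, **kw)


@pytest.fixture
def epoch_pair(rng):
    """Two 4-channel, 50-trial condition blocks; channels 0-1 of condition B
    carry a +1.2 µV window-wide shift, channels 2-3 carry none."""
    n_ch, n_t, n_tr = 4, 30, 50
    a = rng.normal(0.0, 1.0, size=(n_ch, n_t, n_tr))
    b = rng.normal(0.0, 1.0, size=(n_ch, n_t, n_tr))
    b[:2] += 1.2
    return make_epochs(a, condition="A"), make_epochs(b, condition="B")
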