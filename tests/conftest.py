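import logging

import numpy as np
import pytest

from doc_eeg.recording import EEGRecording

logging.getLogger("doc_eeg").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=100.0, channels=None, **kw):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if channels is None:
        channels = ["Cz", "Pz", "C3", "C4", "F3", "F4"][: data.shape[0]]
    defaults = dict(subject_id="test", group=None, state=None)
    defaults.update(kw)
    return EEGRecording(fs=fs, channels=channels, data=data, **defaults)


@pytest.fixture
def noise_recording(rng):
    """Four channels of unit white noise, 60 s at 100 Hz."""
    return make_recording(rng.standard_normal((4, 6000)), fs=100.0)
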