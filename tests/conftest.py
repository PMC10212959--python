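import numpy as np
import pytest

from coughvc.acoustics import MicrophoneModel, Waveform


@pytest.fixture
def mic():
    return MicrophoneModel()


def make_tone(freq, fs=20000.0, duration=1.0, amplitude=1.0, pid="T", trial=0):
    t = np.arange(int(duration * fs)) / fs
    return Waveform(
        samples=amplitude * np.sin(2 * np.pi * freq * t),
        fs=fs,
        participant_id=pid,
        trial_index=trial,
    )


@pytest.fixture
def tone_factory():
    return make_tone
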