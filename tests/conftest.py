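import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def make_recording(signal, sample_rate=1000.0, n_channels=1, **kwargs):
    """Tile a 1-D signal across channels into an EEGRecording."""
    from eyepatch import EEGRecording

    samples = np.tile(np.asarray(signal, dtype=float), (n_channels, 1))
    return EEGRecording(samples=samples, sample_rate=sample_rate, **kwargs)


@pytest.fixture
def sinusoid():
    def _make(freq, amp=1.0, duration=7.0, sample_rate=1000.0, phase=0.0):
        t = np.arange(int(duration * sample_rate)) / sample_rate
        return amp * np.sin(2 * np.pi * freq * t + phase)

    return _make
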