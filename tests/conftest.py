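import numpy as np
import pytest

from chaosaudio.audio import SEGMENT_SAMPLES, AudioSegment

SR = 22_050


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_segment(samples, participant="P01", index=0):
    """Wrap a waveform (padded/truncated to 5 s) as an AudioSegment."""
    x = np.zeros(SEGMENT_SAMPLES)
    samples = np.asarray(samples, dtype=float)
    x[: min(samples.size, SEGMENT_SAMPLES)] = samples[:SEGMENT_SAMPLES]
    return AudioSegment(participant, index, x, float(index * 5))


@pytest.fixture
def sine_segment():
    t = np.arange(SEGMENT_SAMPLES) / SR
    return make_segment(0.5 * np.sin(2 * np.pi * 440.0 * t))


@pytest.fixture
def noise_segment(rng):
    return make_segment(np.clip(rng.normal(0.0, 0.1, SEGMENT_SAMPLES), -1, 1))


@pytest.fixture
def zero_segment():
    return make_segment(np.zeros(SEGMENT_SAMPLES))
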