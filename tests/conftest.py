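import numpy as np
import pytest

from mbcl.cropping import CropSet, slide
from mbcl.signals import EpochSet, Recording
from mbcl.synthetic import SynthConfig, generate_erd_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_synth_config():
    """Small but learnable 3-class ERD setting used across training tests."""
    return SynthConfig(n_classes=3, trials_per_class=12, n_channels=4,
                       fs=64.0, trial_s=2.0, erd_depth=0.8,
                       channels_per_class=1, seed=7)


@pytest.fixture
def tiny_epochs(tiny_synth_config):
    return generate_erd_dataset(tiny_synth_config)


@pytest.fixture
def tiny_crops(tiny_epochs):
    return slide(tiny_epochs, window_s=1.0, stride_s=0.25)


@pytest.fixture
def sine_recording():
    """Two-channel recording: 10 Hz and 60 Hz sines at 512 Hz."""
    fs = 512.0
    t = np.arange(int(fs * 4)) / fs
    data = np.vstack([np.sin(2 * np.pi * 10 * t),
                      np.sin(2 * np.pi * 60 * t)])
    return Recording(data=data, fs=fs, channel_names=["a", "b"],
                     events=[(0, 1), (512, 2), (1024, 1)])


def fft_amplitude(x: np.ndarray, fs: float, freq: float) -> float:
    """Single-bin FFT amplitude oracle for pure-tone filter checks."""
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return float(spec[np.argmin(np.abs(freqs - freq))])
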