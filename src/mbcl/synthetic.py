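"""Synthetic epoched EEG with class-dependent mu-band desynchronization.

Motor imagery suppresses the power of the mu rhythm (~8-12 Hz) over
class-specific sensorimotor electrodes (event-related desynchronization,
ERD).  The generator emulates exactly that statistical structure: every
trial is 1/f-shaped Gaussian background noise plus a narrow-band stochastic
mu oscillation (band-limited Gaussian noise — like the real rhythm, it has
no stable frequency or phase a classifier could memorize) whose amplitude
at a class's designated channels is attenuated by ``erd_depth`` — so an
amplitude attenuation of d reduces band power by the factor (1-d)^2.  The
ERD is stationary within a trial.

The in-band SNR parameter is the ratio of oscillation band power to the
background power falling inside the mu band on an unattenuated channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import EpochSet, Recording

__all__ = ["SynthConfig", "generate_erd_dataset", "make_oracle_probs",
           "class_channel_map", "synthetic_recording"]


@dataclass
class SynthConfig:
    """Generator settings.  Defaults mirror a 16-channel, 128 Hz, 6-class
    motor-imagery setting with 6-second trials."""

    n_classes: int = 6
    trials_per_class: int = 20
    n_channels: int = 16
    fs: float = 128.0
    trial_s: float = 6.0
    mu_band: tuple[float, float] = (8.0, 12.0)
    erd_depth: float = 0.8
    noise_exponent: float = 1.0
    snr: float = 3.0
    seed: int = 0
    channels_per_class: int = 2

    def __post_init__(self):
        if not 0 <= self.erd_depth <= 1:
            raise ValueError("erd_depth must be in [0, 1]")
        if self.fs <= 2 * self.mu_band[1]:
            raise ValueError("sampling rate must exceed twice the mu band")
        if self.trials_per_class < 1:
            raise ValueError("need at least one trial per class")


def iia_like_config(**kw) -> SynthConfig:
    """22-channel, 250 Hz, 4-class preset."""
    base = dict(n_classes=4, n_channels=22, fs=250.0, trial_s=4.0)
    base.update(kw)
    return SynthConfig(**base)


def class_channel_map(cfg: SynthConfig) -> np.ndarray:
    """(n_classes, n_channels) attenuation depths: each class suppresses the
    mu amplitude on its own round-robin block of channels."""
    depth = np.zeros((cfg.n_classes, cfg.n_channels))
    for c in range(cfg.n_classes):
        for j in range(cfg.channels_per_class):
            ch = (c * cfg.channels_per_class + j) % cfg.n_channels
            depth[c, ch] = cfg.erd_depth
    return depth


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n: int,
                      fs: float, exponent: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to f^-exponent."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # zero-mean
    spec = (rng.standard_normal((n_channels, len(freqs)))
            + 1j * rng.standard_normal((n_channels, len(freqs)))) * shaping
    x = np.fft.irfft(spec, n=n, axis=1)
    return x / x.std(axis=1, keepdims=True)


def _band_noise_power(fs: float, n: int, exponent: float,
                      band: tuple[float, float]) -> float:
    """Fraction of unit-variance shaped-noise power inside ``band``."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.zeros_like(freqs)
    nz = freqs > 0
    psd[nz] = freqs[nz] ** (-exponent)
    psd /= psd.sum()
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    return float(psd[in_band].sum())


def _mu_band_noise(rng: np.random.Generator, n_channels: int, n: int,
                   fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise: a stochastic narrow-band
    rhythm with no stable frequency or phase across trials."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = ((freqs >= band[0]) & (freqs <= band[1])).astype(float)
    spec = (rng.standard_normal((n_channels, len(freqs)))
            + 1j * rng.standard_normal((n_channels, len(freqs)))) * mask
    x = np.fft.irfft(spec, n=n, axis=1)
    return x / x.std(axis=1, keepdims=True)


def generate_erd_dataset(cfg: SynthConfig) -> EpochSet:
    """Balanced multi-class epoched dataset; deterministic under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.trial_s * cfg.fs))
    depth = class_channel_map(cfg)
    # oscillation amplitude so that, unattenuated, the rhythm's band power
    # is cfg.snr times the background power inside the mu band
    band_frac = _band_noise_power(cfg.fs, n, cfg.noise_exponent, cfg.mu_band)
    amp = np.sqrt(cfg.snr * band_frac)
    n_trials = cfg.n_classes * cfg.trials_per_class
    labels = np.repeat(np.arange(cfg.n_classes), cfg.trials_per_class)
    epochs = np.empty((n_trials, cfg.n_channels, n))
    for i, y in enumerate(labels):
        bg = _one_over_f_noise(rng, cfg.n_channels, n, cfg.fs,
                               cfg.noise_exponent)
        osc = _mu_band_noise(rng, cfg.n_channels, n, cfg.fs, cfg.mu_band)
        gain = amp * (1.0 - depth[y])[:, None]
        epochs[i] = bg + gain * osc
    order = rng.permutation(n_trials)
    return EpochSet(epochs=epochs[order], labels=labels[order], fs=cfg.fs,
                    class_names=[f"mi{c}" for c in range(cfg.n_classes)])


def synthetic_recording(cfg: SynthConfig, gap_s: float = 1.0,
                        code_offset: int = 769) -> Recording:
    """Continuous recording laying the generated trials end to end with
    event markers at each trial onset (codes ``code_offset + label``).

    Useful for exercising the epoching and container round-trip paths on
    data with known class structure.
    """
    ep = generate_erd_dataset(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    gap = int(round(gap_s * cfg.fs))
    n_tr, n_ch, n = ep.epochs.shape
    total = n_tr * (n + gap) + gap
    data = 0.1 * rng.standard_normal((n_ch, total))
    events = []
    for i in range(n_tr):
        start = gap + i * (n + gap)
        data[:, start:start + n] = ep.epochs[i]
        events.append((start, code_offset + int(ep.labels[i])))
    return Recording(data=data, fs=cfg.fs,
                     channel_names=[f"ch{i}" for i in range(n_ch)],
                     events=events)


def make_oracle_probs(n_learners: int, n_samples: int, n_classes: int,
                      oracle_index: int, noise_level: float = 0.0,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Probability tensor fixture for voting experiments.

    The learner at ``oracle_index`` concentrates mass on the true class
    (perfect at noise_level 0); all other learners emit uninformative
    symmetric-Dirichlet rows.
    Returns (B x N x cls tensor, truth labels).
    """
    if not 0 <= oracle_index < n_learners:
        raise ValueError("oracle_index out of range")
    rng = np.random.default_rng(seed)
    truth = rng.integers(0, n_classes, size=n_samples)
    probs = rng.dirichlet(np.ones(n_classes),
                          size=(n_learners, n_samples))
    onehot = np.eye(n_classes)[truth]
    noisy = (1.0 - noise_level) * onehot \
        + noise_level * rng.dirichlet(np.ones(n_classes), size=n_samples)
    probs[oracle_index] = noisy
    probs /= probs.sum(axis=2, keepdims=True)
    return probs, truth
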