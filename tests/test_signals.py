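"""Preprocessing: filters against FFT oracles, EMS against a per-sample
loop, epoching, containers."""

import numpy as np
import pytest

from mbcl.signals import (EpochSet, FormatError, NoEventsError, Recording,
                          bandpass_filter, decimate, ems_standardize,
                          ems_standardize_epochs, epoch_recording,
                          notch_filter, preprocess_tohoku, read_recording,
                          write_array_bundle)

from conftest import fft_amplitude


def _tone(freq, fs, seconds=4.0):
    t = np.arange(int(fs * seconds)) / fs
    return np.sin(2 * np.pi * freq * t)


# ---------------------------------------------------------------------------
# Recording data model


def test_recording_validates_geometry_and_events():
    with pytest.raises(ValueError):
        Recording(np.zeros((2, 10)), fs=100.0, channel_names=["a"])
    with pytest.raises(ValueError):
        Recording(np.zeros((1, 10)), fs=100.0, channel_names=["a"],
                  events=[(10, 1)])
    with pytest.raises(ValueError):
        Recording(np.zeros((1, 10)), fs=-1.0, channel_names=["a"])


# ---------------------------------------------------------------------------
# Containers


def test_array_bundle_round_trip(tmp_path, sine_recording):
    path = tmp_path / "rec.npz"
    write_array_bundle(path, sine_recording)
    back = read_recording(path, "array-bundle")
    assert np.allclose(back.data, sine_recording.data)
    assert back.fs == sine_recording.fs
    assert back.events == sine_recording.events
    assert back.channel_names == sine_recording.channel_names


def test_minimal_edf_reads_with_events(tmp_path):
    from edf_fixtures import write_minimal_edf

    path = tmp_path / "ok.edf"
    write_minimal_edf(path, n_channels=2, fs=100, seconds=2,
                      annotations=[(0.5, "769"), (1.0, "770")])
    rec = read_recording(path, "edf")
    assert rec.n_channels == 2
    assert rec.fs == 100.0
    codes = [c for _, c in rec.events]
    assert 769 in codes and 770 in codes


def test_corrupt_edf_raises_format_error(tmp_path):
    """A header declaring more channels than the file provides must fail
    as a format error naming the file."""
    from edf_fixtures import write_minimal_edf

    path = tmp_path / "bad.edf"
    write_minimal_edf(path, n_channels=2, fs=100, seconds=2,
                      annotations=[(0.5, "769")], declared_channels=4)
    with pytest.raises(FormatError, match="bad.edf"):
        read_recording(path, "edf")


def test_annotation_free_edf_raises_no_events(tmp_path):
    from edf_fixtures import write_minimal_edf

    path = tmp_path / "plain.edf"
    write_minimal_edf(path, n_channels=1, fs=100, seconds=1, annotations=None)
    with pytest.raises(NoEventsError):
        read_recording(path, "edf")


# ---------------------------------------------------------------------------
# Filters (FFT amplitude oracles)


def test_bandpass_preserves_in_band_tone():
    fs = 250.0
    rec = Recording(_tone(10, fs)[None, :], fs, ["c"])
    out = bandpass_filter(rec, 3, 4.0, 38.0)
    ratio = fft_amplitude(out.data[0], fs, 10) / fft_amplitude(
        rec.data[0], fs, 10)
    assert 0.95 <= ratio <= 1.05


def test_bandpass_rejects_out_of_band_tone():
    fs = 512.0
    rec = Recording(_tone(60, fs)[None, :], fs, ["c"])
    out = bandpass_filter(rec, 8, 0.5, 30.0)
    assert np.sqrt((out.data ** 2).mean()) < 0.05 * np.sqrt(
        (rec.data ** 2).mean())


def test_filters_pass_zero_signal_through():
    rec = Recording(np.zeros((2, 1024)), 512.0, ["a", "b"])
    assert np.allclose(bandpass_filter(rec, 8, 0.5, 30.0).data, 0)
    assert np.allclose(notch_filter(rec, 4, 50.0).data, 0)


def test_bandpass_rejects_cutoff_at_nyquist():
    rec = Recording(np.zeros((1, 100)), 100.0, ["a"])
    with pytest.raises(ValueError):
        bandpass_filter(rec, 3, 4.0, 50.0)


def test_notch_suppresses_center_and_keeps_neighbors():
    # 8 s tone so steady-state attenuation dominates the edge transients
    fs = 512.0
    rec50 = Recording(_tone(50, fs, seconds=8.0)[None, :], fs, ["c"])
    out50 = notch_filter(rec50, 4, 50.0)
    assert np.sqrt((out50.data ** 2).mean()) < 0.10 * np.sqrt(
        (rec50.data ** 2).mean())
    rec10 = Recording(_tone(10, fs)[None, :], fs, ["c"])
    out10 = notch_filter(rec10, 4, 50.0)
    ratio = fft_amplitude(out10.data[0], fs, 10) / fft_amplitude(
        rec10.data[0], fs, 10)
    assert 0.95 <= ratio <= 1.05


def test_filter_linearity(rng):
    fs = 128.0
    x = rng.standard_normal((1, 512))
    y = rng.standard_normal((1, 512))
    a, b = 2.3, -0.7

    def f(sig):
        return bandpass_filter(Recording(sig, fs, ["c"]), 4, 1.0, 40.0).data

    assert np.abs(f(a * x + b * y) - (a * f(x) + b * f(y))).max() < 1e-8


# ---------------------------------------------------------------------------
# Decimation


def test_decimate_halves_rate_and_rescales_events():
    fs = 512.0
    rec = Recording(np.zeros((1, 3072)), fs, ["c"], events=[(512, 7)])
    out = decimate(rec, 4)
    assert out.fs == 128.0
    assert out.data.shape == (1, 768)
    assert out.events == [(128, 7)]


def test_decimate_factor_one_is_identity(sine_recording):
    out = decimate(sine_recording, 1)
    assert np.array_equal(out.data, sine_recording.data)
    with pytest.raises(ValueError):
        decimate(sine_recording, 0)


def test_decimate_preserves_low_frequency_tone():
    fs = 512.0
    rec = Recording(_tone(5, fs)[None, :], fs, ["c"])
    out = decimate(rec, 4)
    ratio = fft_amplitude(out.data[0], 128.0, 5) / fft_amplitude(
        rec.data[0], fs, 5)
    assert 0.95 <= ratio <= 1.05


def test_decimate_composes(rng):
    fs = 512.0
    # band-limited input: low-passed noise
    rec = Recording(rng.standard_normal((1, 4096)), fs, ["c"])
    rec = bandpass_filter(rec, 6, 1.0, 12.0)
    a = decimate(decimate(rec, 2), 2)
    b = decimate(rec, 4)
    rms = np.sqrt((b.data ** 2).mean())
    assert np.sqrt(((a.data - b.data) ** 2).mean()) < 0.02 * rms


# ---------------------------------------------------------------------------
# Exponential moving standardization


def _ems_naive(trial, alpha, eps):
    trial = np.atleast_2d(trial)
    mu = trial.mean(axis=1)
    var = trial.var(axis=1)
    out = np.zeros_like(trial, dtype=float)
    for k in range(trial.shape[1]):
        mu = (1 - alpha) * trial[:, k] + alpha * mu
        var = (1 - alpha) * (trial[:, k] - mu) ** 2 + alpha * var
        out[:, k] = (trial[:, k] - mu) / np.sqrt(np.maximum(var, eps))
    return out


def test_ems_constant_channel_maps_to_zeros():
    out = ems_standardize(np.full((1, 50), 5.0))
    assert np.allclose(out, 0.0)


def test_ems_matches_naive_per_sample_loop(rng):
    trial = rng.standard_normal((3, 200)) * 40 + 12
    for alpha in (0.9, 0.999):
        vec = ems_standardize(trial, alpha=alpha)
        assert np.abs(vec - _ems_naive(trial, alpha, 1e-8)).max() < 1e-10


def test_ems_standardizes_long_white_noise():
    x = np.random.default_rng(3).standard_normal((1, 100_000))
    out = ems_standardize(x, alpha=0.999)
    assert -0.1 < out.mean() < 0.1
    assert 0.8 < out.var() < 1.2


def test_ems_invariant_to_per_channel_affine_rescale(rng):
    trial = rng.standard_normal((2, 300))
    scaled = trial * np.array([[3.5], [0.2]]) + np.array([[-7.0], [4.0]])
    assert np.abs(ems_standardize(trial) - ems_standardize(scaled)).max() < 1e-8


def test_ems_rejects_empty_trial():
    with pytest.raises(ValueError):
        ems_standardize(np.empty((2, 0)))


def test_ems_epochs_applies_per_trial(tiny_epochs):
    out = ems_standardize_epochs(tiny_epochs)
    assert out.epochs.shape == tiny_epochs.epochs.shape
    first = ems_standardize(tiny_epochs.epochs[0])
    assert np.allclose(out.epochs[0], first)


# ---------------------------------------------------------------------------
# Epoching


def test_epoching_basic_counts():
    fs = 100.0
    rec = Recording(np.arange(1000, dtype=float).reshape(1, -1) / 1000, fs,
                    ["c"], events=[(100, 1), (500, 2)])
    ep = epoch_recording(rec, {1, 2}, 0.0, 1.0)
    assert ep.epochs.shape == (2, 1, 100)
    assert ep.labels.tolist() == [0, 1]


def test_epoching_out_of_bounds_names_trial():
    rec = Recording(np.zeros((1, 100)), 100.0, ["c"], events=[(99, 1)])
    with pytest.raises(ValueError, match="trial 0"):
        epoch_recording(rec, {1}, 0.0, 1.0)


def test_epoching_label_order_follows_events():
    codes = [769, 771, 770, 772, 769]
    rec = Recording(np.zeros((1, 2000)), 100.0, ["c"],
                    events=[(i * 300, c) for i, c in enumerate(codes)])
    cmap = {769: 0, 770: 1, 771: 2, 772: 3}
    ep = epoch_recording(rec, cmap, 0.0, 2.0)
    assert ep.labels.tolist() == [0, 2, 1, 3, 0]


def test_epoching_reconstructs_contiguous_partition():
    """Epoching a marker-free partition and concatenating the epochs must
    reproduce the covered samples exactly."""
    fs = 100.0
    data = np.arange(600, dtype=float).reshape(1, -1)
    rec = Recording(data, fs, ["c"], events=[(0, 1), (200, 2), (400, 1)])
    ep = epoch_recording(rec, {1, 2}, 0.0, 2.0)
    rebuilt = np.concatenate(list(ep.epochs), axis=1)
    assert np.array_equal(rebuilt, data)


def test_tohoku_chain_geometry():
    fs = 512.0
    rec = Recording(np.random.default_rng(0).standard_normal((16, 3072)),
                    fs, [f"ch{i}" for i in range(16)])
    out = preprocess_tohoku(rec)
    assert out.fs == 128.0
    assert out.data.shape == (16, 768)
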