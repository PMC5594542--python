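"""Conditioning chain: channel selection, resampling, filters, CAR, epochs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mfload import (ChannelMatrix, Recording, bandpass_eeg,
                    common_average_reference, downsample, epoch, notch,
                    select_channels)
from mfload.containers import EVENT_COLUMNS
from mfload.errors import (ChannelSelectionError, ConfigError, EpochingError)
from mfload.montage import EMG_LABEL, EXCLUDED, FULL_64, SCALP_60


def _recording(labels, n=1000, fs=1000.0, seed=0):
    rng = np.random.default_rng(seed)
    events = pd.DataFrame(columns=list(EVENT_COLUMNS))
    return Recording(rng.standard_normal((len(labels), n)), fs,
                     tuple(labels), events)


def _sine_matrix(freq, fs=1000.0, seconds=4.0, n_ch=2):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return ChannelMatrix(data, fs, tuple(f"ch{i}" for i in range(n_ch)))


def _steady_amplitude(x):
    """Peak amplitude away from filter edges."""
    n = x.shape[-1]
    return np.abs(x[..., n // 4: 3 * n // 4]).max()


class TestSelectChannels:
    def test_full_montage_plus_emg_yields_60_rows(self):
        rec = _recording(FULL_64 + (EMG_LABEL,))
        out = select_channels(rec)
        assert out.data.shape[0] == 60
        assert set(out.labels) == set(SCALP_60)

    def test_already_selected_input_is_identity(self):
        rec = _recording(SCALP_60)
        out = select_channels(rec)
        assert out.labels == tuple(SCALP_60)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_shuffled_order_preserved_and_matches_set_difference(self):
        rng = np.random.default_rng(7)
        shuffled = tuple(rng.permutation(FULL_64 + (EMG_LABEL,)))
        rec = _recording(shuffled)
        out = select_channels(rec)
        expected = [lb for lb in shuffled
                    if lb not in set(EXCLUDED) | {EMG_LABEL}]
        assert list(out.labels) == expected

    def test_missing_required_labels_raises_listing_them(self):
        rec = _recording(("C3", "C4"))
        with pytest.raises(ChannelSelectionError, match="CZ"):
            select_channels(rec, require=("C3", "CZ"))


class TestDownsample:
    def test_sample_count_arithmetic(self):
        x = ChannelMatrix(np.zeros((2, 6000)), 1000.0, ("a", "b"))
        y = downsample(x, 200.0)
        assert y.data.shape == (2, 1200)
        assert y.fs == 200.0

    def test_in_band_sinusoid_amplitude_preserved(self):
        x = _sine_matrix(10.0)
        y = downsample(x, 200.0)
        assert _steady_amplitude(y.data) == pytest.approx(1.0, rel=0.01)

    def test_dc_preserved(self):
        x = ChannelMatrix(np.full((1, 5000), 3.7), 1000.0, ("a",))
        y = downsample(x, 200.0)
        np.testing.assert_allclose(y.data, 3.7, rtol=1e-3)

    def test_non_integer_ratio_rejected(self):
        x = ChannelMatrix(np.zeros((1, 1000)), 1000.0, ("a",))
        with pytest.raises(ConfigError):
            downsample(x, 300.0)


class TestBandpass:
    def test_passband_and_stopband(self):
        kept = bandpass_eeg(_sine_matrix(15.0), 8, 30)
        assert _steady_amplitude(kept.data) >= 0.95
        removed = bandpass_eeg(_sine_matrix(50.0), 8, 30)
        assert _steady_amplitude(removed.data) <= 0.10

    def test_zero_in_zero_out(self):
        x = ChannelMatrix(np.zeros((2, 1000)), 1000.0, ("a", "b"))
        np.testing.assert_array_equal(bandpass_eeg(x).data, 0.0)

    def test_invalid_edges_rejected(self):
        x = _sine_matrix(10.0)
        with pytest.raises(ConfigError):
            bandpass_eeg(x, 30, 8)
        with pytest.raises(ConfigError):
            bandpass_eeg(x, 8, 600)


class TestNotch:
    def test_line_frequency_removed_neighbours_kept(self):
        assert _steady_amplitude(notch(_sine_matrix(50.0)).data) <= 0.05
        assert _steady_amplitude(notch(_sine_matrix(10.0)).data) >= 0.99

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ConfigError):
            notch(_sine_matrix(10.0), f0=600.0)


class TestCAR:
    def test_zero_mean_input_unchanged(self):
        x = ChannelMatrix(np.array([[1.0], [-1.0]]), 100.0, ("a", "b"))
        np.testing.assert_array_equal(
            common_average_reference(x).data, x.data)

    def test_identical_channels_become_zero(self):
        x = ChannelMatrix(np.ones((4, 10)), 100.0, tuple("abcd"))
        np.testing.assert_array_equal(common_average_reference(x).data, 0.0)

    def test_matches_loop_oracle(self, rng):
        data = rng.standard_normal((4, 3))
        out = common_average_reference(
            ChannelMatrix(data, 100.0, tuple("abcd"))).data
        expected = np.empty_like(data)
        for j in range(data.shape[1]):
            col_mean = sum(data[i, j] for i in range(4)) / 4
            for i in range(4):
                expected[i, j] = data[i, j] - col_mean
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ConfigError):
            common_average_reference(
                ChannelMatrix(np.ones((1, 5)), 100.0, ("a",)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(arrays(np.float64, (5, 7),
                  elements=st.floats(-1e6, 1e6, allow_nan=False)))
    def test_column_sums_zero_and_idempotent(self, data):
        x = ChannelMatrix(data, 100.0, tuple("abcde"))
        once = common_average_reference(x)
        scale = max(1.0, np.abs(data).max())
        assert np.abs(once.data.sum(axis=0)).max() <= 1e-9 * scale
        twice = common_average_reference(once)
        np.testing.assert_allclose(twice.data, once.data,
                                   rtol=1e-12, atol=1e-9 * scale)

    def test_commutes_with_linear_filtering(self, rng):
        data = rng.standard_normal((6, 2000))
        x = ChannelMatrix(data, 200.0, tuple("abcdef"))
        a = common_average_reference(bandpass_eeg(x, 8, 30))
        b = bandpass_eeg(common_average_reference(x), 8, 30)
        np.testing.assert_allclose(a.data, b.data, atol=1e-6)


class TestEpoch:
    @staticmethod
    def _events():
        rows = []
        for k, (onset, label) in enumerate([(2.0, "high"), (14.0, "low"),
                                            (26.0, "high")]):
            rows.append({"onset_s": onset, "duration_s": 6.0,
                         "segment": "MI", "label": label,
                         "session": 1, "block": 0, "trial": k})
        rows.append({"onset_s": 10.0, "duration_s": 4.0, "segment": "rest",
                     "label": "high", "session": 1, "block": 0, "trial": 0})
        return pd.DataFrame(rows)

    def test_epoch_count_window_and_labels(self, rng):
        x = ChannelMatrix(rng.standard_normal((3, 200 * 40)), 200.0,
                          ("C3", "CZ", "C4"))
        ep = epoch(x, self._events(), (0.0, 6.0), "MI")
        assert ep.data.shape == (3, 3, 1200)
        assert list(ep.labels) == ["high", "low", "high"]
        assert ep.times[0] == 0.0

    def test_pre_onset_window_length_and_time_axis(self, rng):
        x = ChannelMatrix(rng.standard_normal((2, 200 * 40)), 200.0,
                          ("C3", "C4"))
        ep = epoch(x, self._events(), (-2.0, 6.0), "MI")
        assert ep.n_samples == 1600
        assert ep.times[0] == pytest.approx(-2.0)

    def test_samples_are_half_open_slices_of_the_source(self):
        data = np.arange(200 * 40, dtype=float)[None, :]
        x = ChannelMatrix(data, 200.0, ("C3",))
        ep = epoch(x, self._events(), (0.0, 6.0), "MI")
        np.testing.assert_array_equal(
            ep.data[0, 0], data[0, 400:1600])

    def test_empty_window_rejected(self, rng):
        x = ChannelMatrix(rng.standard_normal((2, 8000)), 200.0, ("a", "b"))
        with pytest.raises(EpochingError):
            epoch(x, self._events(), (0.0, 0.0), "MI")

    def test_out_of_bounds_window_names_trial(self, rng):
        x = ChannelMatrix(rng.standard_normal((2, 200 * 30)), 200.0,
                          ("a", "b"))
        with pytest.raises(EpochingError, match="trial 2"):
            epoch(x, self._events(), (0.0, 6.0), "MI")
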