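"""Recording I/O, zero-phase filters, state-window extraction."""

import numpy as np
import pytest

from wicaeeg.preproc import (
    Recording,
    RecordingError,
    bandpass_filter,
    extract_state_windows,
    notch_filter,
    read_recording,
    rereference_mastoids,
    trim_edges,
    write_recording,
)


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


def interior(data, fs, edge_s=1.0):
    n = int(edge_s * fs)
    return data[:, n:-n]


class TestRecording:
    def test_rejects_single_channel_and_nonfinite(self):
        with pytest.raises(RecordingError):
            Recording(data=np.zeros((1, 10)), fs=100.0)
        bad = np.zeros((2, 10))
        bad[0, 3] = np.nan
        with pytest.raises(RecordingError):
            Recording(data=bad, fs=100.0)

    def test_duration(self):
        rec = Recording(data=np.zeros((2, 500)), fs=250.0)
        assert rec.duration == 2.0


class TestIO:
    def test_roundtrip_delimited(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = Recording(data=rng.standard_normal((3, 200)), fs=250.0,
                        channel_labels=["F01", "E02", "E03"], reference="test")
        path = write_recording(rec, tmp_path / "rec.tsv")
        back = read_recording(path)
        np.testing.assert_allclose(back.data, rec.data, rtol=1e-9)
        assert back.fs == rec.fs
        assert back.channel_labels == rec.channel_labels

    def test_ragged_row_error_names_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\n1\t2\n3\t4\t5\n")
        with pytest.raises(RecordingError, match="row 3"):
            read_recording(p, fs=100.0)

    def test_missing_fs_and_unknown_format(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("a\tb\n1\t2\n")
        with pytest.raises(RecordingError, match="sampling rate"):
            read_recording(p)
        with pytest.raises(RecordingError, match="unknown recording format"):
            read_recording(p, fmt="wav")

    def test_missing_file(self, tmp_path):
        with pytest.raises(RecordingError, match="no such file"):
            read_recording(tmp_path / "nope.tsv")


class TestFilters:
    def test_notch_attenuates_50hz_by_30db(self, sine_recording):
        rec = sine_recording(50.0, fs=500.0)
        out = notch_filter(rec, 50.0)
        ratio = rms(interior(out.data, 500)) / rms(interior(rec.data, 500))
        assert 20 * np.log10(ratio) <= -30

    def test_notch_preserves_dc_and_10hz(self, sine_recording):
        dc = Recording(data=np.full((2, 5000), 7.5), fs=500.0)
        out = notch_filter(dc, 50.0)
        assert np.max(np.abs(out.data - dc.data)) < 1e-6
        rec = sine_recording(10.0, fs=500.0)
        out = notch_filter(rec, 50.0)
        assert rms(interior(out.data, 500)) == pytest.approx(rms(interior(rec.data, 500)), rel=0.01)

    def test_notch_rejects_frequency_at_or_above_nyquist(self, sine_recording):
        rec = sine_recording(10.0, fs=100.0)
        with pytest.raises(RecordingError):
            notch_filter(rec, 50.0)

    def test_bandpass_passband_unity_stopband_20db(self, sine_recording):
        rec10 = sine_recording(10.0, fs=500.0)
        out10 = bandpass_filter(rec10, 0.1, 40.0)
        assert rms(interior(out10.data, 500)) == pytest.approx(
            rms(interior(rec10.data, 500)), rel=0.01
        )
        rec80 = sine_recording(80.0, fs=500.0)
        out80 = bandpass_filter(rec80, 0.1, 40.0)
        ratio = rms(interior(out80.data, 500)) / rms(interior(rec80.data, 500))
        assert 20 * np.log10(ratio) <= -20

    def test_bandpass_zero_in_zero_out_and_bad_band(self, sine_recording):
        zero = Recording(data=np.zeros((2, 1000)), fs=250.0)
        assert np.all(bandpass_filter(zero).data == 0.0)
        with pytest.raises(RecordingError):
            bandpass_filter(sine_recording(10.0, fs=100.0), 40.0, 0.1)

    def test_filters_are_linear(self):
        rng = np.random.default_rng(1)
        x = Recording(data=rng.standard_normal((2, 2000)), fs=250.0)
        y = Recording(data=rng.standard_normal((2, 2000)), fs=250.0)
        combo = Recording(data=2.0 * x.data - 3.0 * y.data, fs=250.0)
        for filt in (lambda r: notch_filter(r, 50.0), lambda r: bandpass_filter(r)):
            lhs = filt(combo).data
            rhs = 2.0 * filt(x).data - 3.0 * filt(y).data
            assert np.max(np.abs(lhs - rhs)) <= 1e-6 * max(np.max(np.abs(lhs)), 1.0)

    def test_zero_phase_pulse_peak_at_zero_lag(self):
        # band-limited pulse: filtered output's cross-correlation with the
        # input must peak at lag zero (no group delay)
        fs = 250.0
        t = np.arange(int(8 * fs)) / fs
        pulse = np.exp(-0.5 * ((t - 4.0) / 0.15) ** 2) * np.sin(2 * np.pi * 10 * (t - 4.0))
        rec = Recording(data=np.vstack([pulse, pulse]), fs=fs)
        out = bandpass_filter(rec, 0.5, 30.0)
        xc = np.correlate(out.data[0], rec.data[0], mode="full")
        lag = np.argmax(xc) - (len(pulse) - 1)
        assert lag == 0


class TestWindowsAndReference:
    def test_five_minute_windows_of_30_min_recording(self):
        fs = 500.0
        n = int(1800 * fs)
        data = np.broadcast_to(np.arange(n, dtype=float), (2, n))
        rec = Recording(data=np.array(data), fs=fs)
        sw = extract_state_windows(rec, 300.0)
        assert sw.alert.n_samples == 150000
        assert sw.alert.data[0, 0] == 0 and sw.alert.data[0, -1] == 149999
        assert sw.decrement.data[0, 0] == 750000 and sw.decrement.data[0, -1] == 899999

    def test_exactly_double_window_is_allowed(self):
        rec = Recording(data=np.zeros((2, 600 * 100)), fs=100.0)
        sw = extract_state_windows(rec, 300.0)
        assert sw.alert.n_samples == sw.decrement.n_samples == 30000

    def test_overlapping_windows_rejected_with_required_duration(self):
        rec = Recording(data=np.zeros((2, 400 * 100)), fs=100.0)
        with pytest.raises(RecordingError, match="600 s"):
            extract_state_windows(rec, 300.0)

    def test_trim_edges(self):
        rec = Recording(data=np.arange(20, dtype=float).reshape(2, 10), fs=1.0)
        out = trim_edges(rec, 2.0)
        assert out.n_samples == 6
        with pytest.raises(RecordingError):
            trim_edges(rec, 5.0)

    def test_mastoid_rereference_only_when_labels_present(self):
        data = np.vstack([np.ones(10), 2 * np.ones(10), 4 * np.ones(10), 6 * np.ones(10)])
        rec = Recording(data=data, fs=100.0, channel_labels=["C1", "C2", "M1", "M2"])
        out = rereference_mastoids(rec)
        assert out.channel_labels == ["C1", "C2"]
        np.testing.assert_allclose(out.data[0], 1 - 5.0)
        rec2 = Recording(data=data[:2], fs=100.0, channel_labels=["C1", "C2"])
        assert rereference_mastoids(rec2) is rec2
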