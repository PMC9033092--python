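"""Recording container, file I/O and fixed EEG pre-filters.

The cleaning front-end is deliberately small: a 50 Hz notch for mains
interference, a 0.1-40 Hz band-pass for the physiological band of interest,
optional linked-mastoid re-referencing, and extraction of the two
fixed-length vigilance-state windows (first and last segment of a
recording).  All filters are applied forward-backward so they are
zero-phase and introduce no group delay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal


class RecordingError(ValueError):
    """Raised for malformed recordings or unreadable recording files."""


@dataclass
class Recording:
    """Multichannel EEG time series.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        One label per channel, order matching the rows of ``data``.
    reference
        Free-text provenance note (e.g. ``"linked mastoids"``).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    reference: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise RecordingError("data must be 2-D (n_channels, n_samples)")
        if self.data.shape[0] < 2:
            raise RecordingError("a Recording needs at least 2 channels")
        if self.data.shape[1] < 1:
            raise RecordingError("a Recording needs at least 1 sample")
        if not self.fs > 0:
            raise RecordingError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"CH{i + 1:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise RecordingError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not np.isfinite(self.data).all():
            raise RecordingError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, reference: str | None = None) -> "Recording":
        return replace(
            self, data=data, reference=self.reference if reference is None else reference
        )


@dataclass
class StateWindows:
    """The alert (first) and vigilance-decrement (last) windows of a recording."""

    alert: Recording
    decrement: Recording
    source_duration: float

    def __post_init__(self) -> None:
        if self.alert.n_samples != self.decrement.n_samples:
            raise RecordingError("state windows must have equal length")
        if self.alert.fs != self.decrement.fs:
            raise RecordingError("state windows must share the sampling rate")


# ---------------------------------------------------------------------------
# I/O: delimited text (+ JSON sidecar) and EDF
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as a TSV matrix (samples x channels) plus JSON sidecar.

    The header row carries the channel labels; the sidecar ``<path>.json``
    carries sampling rate, units and the reference note.
    """
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {"fs": rec.fs, "units": "uV", "reference": rec.reference}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def _read_delimited(path: Path, fs: float | None) -> Recording:
    sidecar_path = Path(str(path) + ".json")
    reference = ""
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        fs = sidecar.get("fs", fs)
        reference = sidecar.get("reference", "")
    if fs is None:
        raise RecordingError(
            f"no sampling rate: pass fs= or provide a sidecar {sidecar_path.name}"
        )
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for i, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise RecordingError(
                    f"{path.name}: row {i} has {len(parts)} fields, expected {len(header)}"
                )
            rows.append(parts)
    try:
        data = np.asarray(rows, dtype=float).T
    except ValueError as exc:
        raise RecordingError(f"{path.name}: non-numeric value ({exc})") from exc
    return Recording(data=data, fs=float(fs), channel_labels=header, reference=reference)


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        reference="as recorded (EDF)",
    )


def read_recording(path: str | Path, fmt: str | None = None, fs: float | None = None) -> Recording:
    """Read a Recording from an EDF file or a delimited-text matrix.

    ``fmt`` is ``"edf"`` or ``"text"``; by default it is inferred from the
    file suffix.  For text files the sampling rate comes from the JSON
    sidecar written by :func:`write_recording`, or from ``fs``.
    """
    path = Path(path)
    if not path.exists():
        raise RecordingError(f"no such file: {path}")
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "text"
    fmt = fmt.lower()
    if fmt == "edf":
        return _read_edf(path)
    if fmt in ("text", "tsv", "csv"):
        return _read_delimited(path, fs)
    raise RecordingError(f"unknown recording format: {fmt!r}")


# ---------------------------------------------------------------------------
# Filters (zero-phase)
# ---------------------------------------------------------------------------

def notch_filter(rec: Recording, f0: float = 50.0, q: float = 30.0) -> Recording:
    """Zero-phase IIR notch at ``f0`` Hz (second-order section, quality ``q``)."""
    if not 0 < f0 < rec.fs / 2:
        raise RecordingError(
            f"notch frequency {f0} Hz must lie below Nyquist ({rec.fs / 2} Hz)"
        )
    b, a = signal.iirnotch(f0, q, fs=rec.fs)
    padlen = int(min(rec.n_samples - 1, 10.0 * rec.fs * q / f0))
    out = signal.filtfilt(b, a, rec.data, axis=1, padtype="even", padlen=padlen)
    return rec.copy_with(out)


def bandpass_filter(rec: Recording, lo: float = 0.1, hi: float = 40.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass between ``lo`` and ``hi`` Hz."""
    if not 0 < lo < hi < rec.fs / 2:
        raise RecordingError(
            f"band ({lo}, {hi}) Hz invalid for fs={rec.fs} (need 0 < lo < hi < Nyquist)"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    # generous even-extension padding: the low cutoff has a multi-second
    # impulse response, and the default (short, odd) padding leaves large
    # low-frequency edge swings that later stages mistake for transients
    padlen = int(min(rec.n_samples - 1, 3.0 * rec.fs / lo))
    out = signal.sosfiltfilt(sos, rec.data, axis=1, padtype="even", padlen=padlen)
    return rec.copy_with(out)


def rereference_mastoids(rec: Recording, mastoid_labels: tuple[str, str] = ("M1", "M2")) -> Recording:
    """Re-reference to linked mastoids when both mastoid channels are present.

    Subtracts the mean of the two mastoid channels from every channel and
    drops the mastoids.  If either label is absent the recording is returned
    unchanged (simulated data is emitted already referenced).
    """
    labels = rec.channel_labels
    if not all(m in labels for m in mastoid_labels):
        return rec
    idx = [labels.index(m) for m in mastoid_labels]
    ref = rec.data[idx].mean(axis=0)
    keep = [i for i in range(rec.n_channels) if i not in idx]
    data = rec.data[keep] - ref
    return Recording(
        data=data,
        fs=rec.fs,
        channel_labels=[labels[i] for i in keep],
        reference="linked mastoids",
    )


def trim_edges(rec: Recording, seconds: float) -> Recording:
    """Drop ``seconds`` from both ends of a recording.

    Zero-phase IIR filtering leaves edge transients (the 0.1 Hz high-pass
    rings for seconds); analyses should run on the interior.
    """
    n = int(round(seconds * rec.fs))
    if n == 0:
        return rec
    if rec.n_samples <= 2 * n:
        raise RecordingError(
            f"cannot trim {seconds} s from each end of a {rec.duration:.1f} s recording"
        )
    return rec.copy_with(rec.data[:, n:rec.n_samples - n].copy())


def extract_state_windows(rec: Recording, window_s: float = 300.0) -> StateWindows:
    """Cut the alert (first ``window_s`` s) and decrement (last ``window_s`` s) windows.

    The two windows must not overlap, so the recording has to be at least
    twice the window length.
    """
    n_win = int(round(window_s * rec.fs))
    if rec.n_samples < 2 * n_win:
        raise RecordingError(
            f"recording of {rec.duration:.1f} s too short: two non-overlapping "
            f"{window_s:.0f} s windows require at least {2 * window_s:.0f} s"
        )
    alert = rec.copy_with(rec.data[:, :n_win].copy())
    decrement = rec.copy_with(rec.data[:, rec.n_samples - n_win:].copy())
    return StateWindows(alert=alert, decrement=decrement, source_duration=rec.duration)
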