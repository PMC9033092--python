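"""Band-limited PSD features on moving windows.

Per 2-second window (1 s hop) and channel, a Hann-tapered periodogram is
integrated over each canonical EEG band — delta (0.1-4 Hz), theta
(4-8 Hz), alpha (8-13 Hz), beta (13-30 Hz) — giving one non-negative band
power per epoch and channel.  Stacking the epochs of the alert and
vigilance-decrement windows yields the labelled per-band datasets fed to
the classifiers.  A 5-minute window at a 1 s hop yields 299 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .preproc import Recording, StateWindows


class FeatureError(ValueError):
    """Raised for invalid feature-extraction requests."""


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise FeatureError(f"band {self.name}: need lo < hi, got ({self.lo}, {self.hi})")


DEFAULT_BANDS = (
    BandDefinition("delta", 0.1, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)


def band_by_name(name: str) -> BandDefinition:
    for band in DEFAULT_BANDS:
        if band.name == name:
            return band
    raise FeatureError(f"unknown band {name!r}")


@dataclass
class FeatureMatrix:
    """Per-epoch, per-channel band power (integrated PSD, uV^2)."""

    values: np.ndarray  # (n_epochs, n_channels)
    band: BandDefinition
    epoch_times: np.ndarray  # window start, seconds
    channel_labels: list[str]

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]


@dataclass
class LabeledDataset:
    """Feature matrix stacked over the two vigilance states with 0/1 labels."""

    x: np.ndarray  # (n_epochs_total, n_channels)
    y: np.ndarray  # 0 = alert, 1 = vigilance decrement
    band: BandDefinition
    channel_labels: list[str]


def band_psd(
    rec: Recording,
    band: BandDefinition,
    window_s: float = 2.0,
    hop_s: float = 1.0,
    taper: str = "hann",
) -> FeatureMatrix:
    """Moving-window band power for every channel.

    Each window's one-sided periodogram is integrated (sum times bin
    width) over ``band.lo <= f < band.hi``; the half-open interval keeps
    adjacent bands disjoint.
    """
    if band.hi >= rec.fs / 2:
        raise FeatureError(
            f"band {band.name} upper edge {band.hi} Hz reaches Nyquist ({rec.fs / 2} Hz)"
        )
    nper = int(round(window_s * rec.fs))
    hop = max(1, int(round(hop_s * rec.fs)))
    if nper > rec.n_samples:
        raise FeatureError(
            f"window of {window_s} s exceeds recording duration {rec.duration:.1f} s"
        )
    win = signal.get_window(taper, nper) if taper != "rectangular" else np.ones(nper)
    starts = np.arange(0, rec.n_samples - nper + 1, hop)
    freqs = np.fft.rfftfreq(nper, d=1.0 / rec.fs)
    mask = (freqs >= band.lo) & (freqs < band.hi)
    df = freqs[1] - freqs[0]
    values = np.empty((starts.size, rec.n_channels))
    for e, s0 in enumerate(starts):
        f, pxx = signal.periodogram(
            rec.data[:, s0:s0 + nper], fs=rec.fs, window=win, detrend=False, axis=1
        )
        values[e] = pxx[:, mask].sum(axis=1) * df
    return FeatureMatrix(
        values=values,
        band=band,
        epoch_times=starts / rec.fs,
        channel_labels=list(rec.channel_labels),
    )


def build_dataset(
    states: StateWindows,
    bands=DEFAULT_BANDS,
    window_s: float = 2.0,
    hop_s: float = 1.0,
    taper: str = "hann",
) -> dict[str, LabeledDataset]:
    """One labelled dataset per band: alert epochs are class 0, decrement class 1."""
    out: dict[str, LabeledDataset] = {}
    for band in bands:
        fa = band_psd(states.alert, band, window_s, hop_s, taper)
        fd = band_psd(states.decrement, band, window_s, hop_s, taper)
        x = np.vstack([fa.values, fd.values])
        y = np.concatenate([np.zeros(fa.n_epochs, dtype=int), np.ones(fd.n_epochs, dtype=int)])
        out[band.name] = LabeledDataset(x=x, y=y, band=band, channel_labels=fa.channel_labels)
    return out


def band_power_table(
    rec: Recording, bands=DEFAULT_BANDS, window_s: float = 2.0, hop_s: float = 1.0
) -> pd.DataFrame:
    """Per-channel, per-band mean power — the data layer behind topographic maps."""
    rows = {}
    for band in bands:
        fm = band_psd(rec, band, window_s, hop_s)
        rows[band.name] = fm.values.mean(axis=0)
    return pd.DataFrame(rows, index=rec.channel_labels)


def features_to_frame(fm: FeatureMatrix, label: str | int | None = None) -> pd.DataFrame:
    """Tidy long-format export: epoch, channel, band, value (+ optional label)."""
    n_e, n_c = fm.values.shape
    frame = pd.DataFrame(
        {
            "epoch_time_s": np.repeat(fm.epoch_times, n_c),
            "channel": np.tile(fm.channel_labels, n_e),
            "band": fm.band.name,
            "band_power": fm.values.ravel(),
        }
    )
    if label is not None:
        frame["label"] = label
    return frame
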