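"""Synthetic multichannel EEG with known neural content and known artifacts.

Real vigilance recordings are rarely shareable, so every downstream stage
here is validated against a simulator that mimics the acquisition setup of
a typical high-density lab study (62 scalp channels, 500 Hz, mastoid
referenced) and provides exact ground truth: the neural-only and
artifact-only mixtures are returned alongside the contaminated one, and
``mixed == neural + artifact`` holds sample-by-sample by construction.

Source model
------------
* Neural sources: independent band-limited Gaussian noise.  Each source is
  a sum of band-passed white-noise processes (delta/theta/alpha/beta), each
  normalised to unit RMS and scaled so the source's band powers match the
  configured relative powers and its total variance is one (times a global
  microvolt scale).
* Blink sources: sparse positive raised-cosine pulses of 300 ms, event
  times a homogeneous Poisson process, mixed predominantly into the
  frontal quartile of channels.
* Muscle sources: Hann-windowed bursts of >20 Hz noise, Poisson event times.
* Line source: a pure 50 Hz sinusoid.
* Sensor noise: independent white noise added per channel (measurement-device
  artifact, so it lives on the artifact track); it is what keeps blind
  source separation realistically imperfect.

A ``state_shift`` scales theta and alpha source power by ``1 + state_shift``,
which is how the vigilance-decrement segment of a two-state dataset is
produced; the mixing matrix is shared bitwise between the two states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .preproc import Recording

#: global scale: RMS of one neural source, in microvolts
NEURAL_RMS_UV = 10.0

#: number of artifact sources of each kind, when the kind is active
N_BLINK_SOURCES = 2
N_MUSCLE_SOURCES = 2
N_LINE_SOURCES = 1

BLINK_PULSE_S = 0.3
MUSCLE_BURST_S = 0.5
LINE_FREQ_HZ = 50.0

DEFAULT_BAND_POWERS = {
    "delta": 1.0,
    "theta": 0.8,
    "alpha": 1.0,
    "beta": 0.5,
}

BAND_EDGES = {
    "delta": (0.1, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


class SimulationConfigError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated recording; identical configs give bitwise-identical output."""

    n_channels: int = 62
    n_sources: int | None = None  # defaults to n_channels (square mixing)
    fs: float = 500.0
    duration: float = 600.0  # seconds
    band_powers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_POWERS))
    blink_rate: float = 6.0  # events / minute
    blink_amplitude: float = 10.0  # pulse peak, multiples of neural source RMS
    muscle_burst_rate: float = 2.0  # events / minute
    muscle_amplitude: float = 5.0  # burst RMS, multiples of neural source RMS
    line_noise_amplitude: float = 2.0  # microvolts at 50 Hz (source level)
    sensor_noise_rms: float = 1.0  # per-channel white measurement noise, microvolts
    mixing_seed: int = 0
    noise_seed: int = 0
    state_shift: float = 0.0  # fractional theta/alpha power change

    def resolved_n_sources(self) -> int:
        return self.n_channels if self.n_sources is None else self.n_sources

    def validate(self) -> None:
        if self.n_channels < 2:
            raise SimulationConfigError("n_channels must be >= 2")
        if self.resolved_n_sources() > self.n_channels:
            raise SimulationConfigError("n_sources must be <= n_channels")
        if not self.fs > 0:
            raise SimulationConfigError("fs must be positive")
        if not self.duration > 0:
            raise SimulationConfigError("duration must be positive")
        for name, p in self.band_powers.items():
            if name not in BAND_EDGES:
                raise SimulationConfigError(f"unknown band in band_powers: {name!r}")
            if p < 0:
                raise SimulationConfigError(f"band_powers[{name!r}] must be >= 0")
        if not any(p > 0 for p in self.band_powers.values()):
            raise SimulationConfigError("band_powers must contain at least one positive entry")
        for fname in ("blink_rate", "blink_amplitude", "muscle_burst_rate",
                      "muscle_amplitude", "line_noise_amplitude", "sensor_noise_rms"):
            if getattr(self, fname) < 0:
                raise SimulationConfigError(f"{fname} must be >= 0")
        if self.state_shift <= -1:
            raise SimulationConfigError(
                "state_shift must be > -1 (theta/alpha power would be non-positive)"
            )
        n_art = self._active_artifact_counts()
        if self.resolved_n_sources() <= sum(n_art.values()):
            raise SimulationConfigError(
                f"n_sources={self.resolved_n_sources()} leaves no neural source "
                f"after {sum(n_art.values())} artifact sources"
            )

    def _active_artifact_counts(self) -> dict[str, int]:
        return {
            "blink": N_BLINK_SOURCES if self.blink_rate > 0 and self.blink_amplitude > 0 else 0,
            "muscle": N_MUSCLE_SOURCES if self.muscle_burst_rate > 0 and self.muscle_amplitude > 0 else 0,
            "line": N_LINE_SOURCES if self.line_noise_amplitude > 0 else 0,
        }


@dataclass
class SyntheticGroundTruth:
    """A simulated recording together with its exact neural/artifact split."""

    mixed: Recording
    neural: Recording
    artifact: Recording
    mixing_matrix: np.ndarray  # (n_channels, n_sources)
    source_kind: list[str]  # per source: neural | blink | muscle | line
    sources: np.ndarray  # (n_sources, n_samples) ground-truth source tracks
    config: SimulationConfig

    def source_indices(self, kind: str) -> list[int]:
        return [i for i, k in enumerate(self.source_kind) if k == kind]


def _channel_labels(n_channels: int) -> list[str]:
    """First quartile of channels is labelled frontal (F..), the rest E.. ."""
    n_front = max(1, n_channels // 4)
    return [
        (f"F{i + 1:02d}" if i < n_front else f"E{i + 1:02d}")
        for i in range(n_channels)
    ]


def frontal_channel_indices(labels: list[str]) -> list[int]:
    return [i for i, lab in enumerate(labels) if lab.startswith("F")]


def _neural_source(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    """One band-limited noise source with calibrated relative band powers.

    At ``state_shift = 0`` the source has unit RMS (times the global
    microvolt scale) and per-band power proportional to ``band_powers``.
    A non-zero shift scales theta and alpha power by ``1 + state_shift``
    *absolutely* — the other bands are untouched, so the decrement state
    differs from alert exactly and only in those two bands.
    """
    powers = dict(cfg.band_powers)
    total = sum(powers.values())
    out = np.zeros(n)
    for band, p in powers.items():
        if p <= 0:
            continue
        if band in ("theta", "alpha"):
            p = p * (1.0 + cfg.state_shift)
        lo, hi = BAND_EDGES[band]
        hi = min(hi, 0.45 * cfg.fs)
        white = rng.standard_normal(n)
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=cfg.fs, output="sos")
        comp = signal.sosfiltfilt(sos, white)
        comp /= np.sqrt(np.mean(comp**2))
        out += np.sqrt(p / total) * comp
    return out * NEURAL_RMS_UV


def _poisson_event_starts(rng: np.random.Generator, rate_per_min: float,
                          duration: float, event_s: float, fs: float) -> np.ndarray:
    """Start samples of a homogeneous Poisson process, events kept inside the record."""
    n_events = rng.poisson(rate_per_min * duration / 60.0)
    latest = duration - event_s
    if n_events == 0 or latest <= 0:
        return np.empty(0, dtype=int)
    starts = np.sort(rng.uniform(0.0, latest, size=n_events))
    return (starts * fs).astype(int)


def _blink_source(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    out = np.zeros(n)
    n_pulse = max(2, int(round(BLINK_PULSE_S * cfg.fs)))
    t = np.arange(n_pulse) / (n_pulse - 1)
    pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * t))  # raised cosine, peak 1
    amp = cfg.blink_amplitude * NEURAL_RMS_UV
    for s0 in _poisson_event_starts(rng, cfg.blink_rate, cfg.duration, BLINK_PULSE_S, cfg.fs):
        out[s0:s0 + n_pulse] += amp * pulse[: n - s0]
    return out


def _muscle_source(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    out = np.zeros(n)
    n_burst = max(8, int(round(MUSCLE_BURST_S * cfg.fs)))
    hi_lo = 20.0
    hi_hi = 0.45 * cfg.fs
    if hi_hi <= hi_lo:  # very low fs: plain high-pass
        sos = signal.butter(4, hi_lo, btype="highpass", fs=cfg.fs, output="sos")
    else:
        sos = signal.butter(4, [hi_lo, hi_hi], btype="bandpass", fs=cfg.fs, output="sos")
    amp = cfg.muscle_amplitude * NEURAL_RMS_UV
    window = signal.windows.hann(n_burst)
    for s0 in _poisson_event_starts(rng, cfg.muscle_burst_rate, cfg.duration, MUSCLE_BURST_S, cfg.fs):
        burst = signal.sosfiltfilt(sos, rng.standard_normal(n_burst)) * window
        rms = np.sqrt(np.mean(burst**2))
        if rms > 0:
            burst *= amp / rms
        out[s0:s0 + n_burst] += burst[: n - s0]
    return out


def _line_source(cfg: SimulationConfig, n: int) -> np.ndarray:
    t = np.arange(n) / cfg.fs
    return cfg.line_noise_amplitude * np.sin(2.0 * np.pi * LINE_FREQ_HZ * t)


def _mixing_matrix(cfg: SimulationConfig, source_kind: list[str]) -> np.ndarray:
    """Column-normalised random mixing; blink columns get a frontal gradient.

    Entries are i.i.d. standard normal; the matrix is resampled if its
    condition number exceeds 1e3 so that ICA stays well-posed.  Blink
    columns decay from the frontal channels down the montage, with mild
    per-channel jitter so two blink sources are not collinear.
    """
    rng = np.random.default_rng(cfg.mixing_seed)
    n_ch = cfg.n_channels
    n_src = len(source_kind)
    gradient = np.exp(-np.arange(n_ch) / max(1.0, n_ch / 8.0))
    for _ in range(50):
        m = rng.standard_normal((n_ch, n_src))
        for j, kind in enumerate(source_kind):
            if kind == "blink":
                jitter = 1.0 + 0.2 * rng.standard_normal(n_ch)
                m[:, j] = gradient * np.abs(jitter)
        m /= np.linalg.norm(m, axis=0, keepdims=True)
        if np.linalg.cond(m) <= 1e3:
            return m
    raise SimulationConfigError("could not draw a well-conditioned mixing matrix")


def simulate_eeg(config: SimulationConfig) -> SyntheticGroundTruth:
    """Generate one ground-truth recording from ``config``.

    Returns the mixed recording plus its exact neural-only and artifact-only
    parts (``mixed = neural + artifact`` holds to the last bit), the mixing
    matrix and the per-source kind labels.
    """
    config.validate()
    n = int(round(config.duration * config.fs))
    n_src = config.resolved_n_sources()
    counts = config._active_artifact_counts()
    source_kind = (
        ["neural"] * (n_src - sum(counts.values()))
        + ["blink"] * counts["blink"]
        + ["muscle"] * counts["muscle"]
        + ["line"] * counts["line"]
    )

    rng = np.random.default_rng(config.noise_seed)
    sources = np.zeros((n_src, n))
    for i, kind in enumerate(source_kind):
        if kind == "neural":
            sources[i] = _neural_source(rng, config, n)
        elif kind == "blink":
            sources[i] = _blink_source(rng, config, n)
        elif kind == "muscle":
            sources[i] = _muscle_source(rng, config, n)
        else:
            sources[i] = _line_source(config, n)

    mixing = _mixing_matrix(config, source_kind)
    neural_mask = np.array([k == "neural" for k in source_kind])
    neural_data = mixing[:, neural_mask] @ sources[neural_mask]
    artifact_data = mixing[:, ~neural_mask] @ sources[~neural_mask]
    if config.sensor_noise_rms > 0:
        # measurement-device noise enters per channel, not through the mixing;
        # it belongs to the artifact track (device artifacts, like mains hum)
        artifact_data = artifact_data + config.sensor_noise_rms * rng.standard_normal(
            (config.n_channels, n)
        )
    labels = _channel_labels(config.n_channels)

    def rec(data: np.ndarray, note: str) -> Recording:
        return Recording(data=data, fs=config.fs, channel_labels=list(labels), reference=note)

    return SyntheticGroundTruth(
        mixed=rec(neural_data + artifact_data, "simulated (mixed)"),
        neural=rec(neural_data, "simulated (neural only)"),
        artifact=rec(artifact_data, "simulated (artifact only)"),
        mixing_matrix=mixing,
        source_kind=source_kind,
        sources=sources,
        config=config,
    )


def make_two_state_dataset(
    config: SimulationConfig,
) -> tuple[SyntheticGroundTruth, SyntheticGroundTruth]:
    """Simulate the alert and vigilance-decrement segments of one subject.

    The alert segment is generated with no power shift; the decrement
    segment scales theta and alpha source power by ``1 + config.state_shift``.
    Both segments share the mixing matrix bitwise (same ``mixing_seed``) and
    use distinct noise streams, so with ``state_shift = 0`` they are
    statistically exchangeable.
    """
    config.validate()
    alert_cfg = replace(config, state_shift=0.0)
    decrement_cfg = replace(config, noise_seed=config.noise_seed + 104729)
    alert = simulate_eeg(alert_cfg)
    decrement = simulate_eeg(decrement_cfg)
    return alert, decrement


def save_ground_truth(truth: SyntheticGroundTruth, out_dir) -> None:
    """Write the three tracks as delimited text plus a JSON sidecar of the run."""
    import json
    from pathlib import Path

    from .preproc import write_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("mixed", "neural", "artifact"):
        write_recording(getattr(truth, name), out / f"{name}.tsv")
    meta = {
        "config": {k: (v if not isinstance(v, dict) else dict(v))
                   for k, v in vars(truth.config).items()},
        "source_kind": truth.source_kind,
        "mixing_matrix": truth.mixing_matrix.tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=1))
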