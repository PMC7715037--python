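"""Seeded synthetic-signal generators: SSVEP-like EEG, gaze trails, artifacts.

These generators stand in for the amplifier and the eye tracker so every
downstream stage (feature extraction, calibration, the speller engine, the
copy-spelling protocol) can be exercised end to end without hardware.

EEG model: attending target ``t`` superposes sinusoids at that target's
stimulation frequency and its harmonics — with per-channel gains and phases —
on independent 1/f-spectrum ("pink") background noise per channel.  The
signal-to-noise ratio ``snr`` is defined as RMS(signal)/RMS(noise) per
channel before summation; ``snr = 0`` yields pure noise and ``snr = inf``
a noise-free trial.

Gaze model: points scattered isotropically (bivariate normal) around the
intended target's center, with i.i.d. Bernoulli dropouts marked invalid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .stimulus import ScreenLayout, StimulusSet

DEFAULT_CHANNELS = ("O1", "Oz", "O2")
DEFAULT_EEG_RATE_HZ = 256.0
DEFAULT_GAZE_RATE_HZ = 60.0

#: Baseline background-noise RMS in microvolts; sets the overall signal scale.
NOISE_RMS_UV = 5.0

#: Amplitude of harmonic h relative to the fundamental (h = 1).
HARMONIC_RATIO = 0.5


@dataclass
class EEGSegment:
    """Fixed-rate multichannel EEG sample block.

    ``samples`` is channels x time in microvolts.  ``quality_flags[c]`` is True
    when channel ``c`` is artifact-contaminated.
    """

    samples: np.ndarray
    rate_hz: float = DEFAULT_EEG_RATE_HZ
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    quality_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match channel count")
        if self.quality_flags is None:
            self.quality_flags = np.zeros(self.samples.shape[0], dtype=bool)
        else:
            self.quality_flags = np.asarray(self.quality_flags, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def truncated(self, duration_s: float) -> "EEGSegment":
        """First ``duration_s`` seconds of the segment (new view-backed object)."""
        n = int(round(duration_s * self.rate_hz))
        if not 0 < n <= self.n_samples:
            raise ValueError(
                f"truncation to {duration_s} s outside recorded {self.duration_s} s"
            )
        return replace(self, samples=self.samples[:, :n].copy(),
                       quality_flags=self.quality_flags.copy())

    def to_csv(self, path: str | Path, metadata: dict | None = None) -> None:
        """One row per sample; JSON sidecar ``<path>.json`` carries metadata."""
        path = Path(path)
        df = pd.DataFrame(self.samples.T, columns=list(self.channel_labels))
        df.insert(0, "time_s", np.arange(self.n_samples) / self.rate_hz)
        df.to_csv(path, index=False, float_format="%.6f")
        meta = {
            "rate_hz": self.rate_hz,
            "channel_labels": list(self.channel_labels),
            "quality_flags": [bool(q) for q in self.quality_flags],
        }
        meta.update(metadata or {})
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "EEGSegment":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        df = pd.read_csv(path)
        labels = tuple(meta["channel_labels"])
        return cls(
            samples=df[list(labels)].to_numpy().T,
            rate_hz=float(meta["rate_hz"]),
            channel_labels=labels,
            quality_flags=np.asarray(meta["quality_flags"], dtype=bool),
        )


@dataclass
class GazeTrail:
    """Timestamped 2-D gaze samples in degrees of visual angle."""

    timestamps: np.ndarray
    points: np.ndarray
    validity: np.ndarray
    rate_hz: float = DEFAULT_GAZE_RATE_HZ

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (len(self.timestamps) == len(self.points) == len(self.validity)):
            raise ValueError("timestamps, points and validity must have equal length")
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    def to_csv(self, path: str | Path, metadata: dict | None = None) -> None:
        path = Path(path)
        df = pd.DataFrame(
            {
                "time_s": self.timestamps,
                "x_deg": self.points[:, 0],
                "y_deg": self.points[:, 1],
                "valid": self.validity.astype(int),
            }
        )
        df.to_csv(path, index=False, float_format="%.6f")
        meta = {"rate_hz": self.rate_hz}
        meta.update(metadata or {})
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "GazeTrail":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        df = pd.read_csv(path)
        return cls(
            timestamps=df["time_s"].to_numpy(),
            points=df[["x_deg", "y_deg"]].to_numpy(),
            validity=df["valid"].to_numpy().astype(bool),
            rate_hz=float(meta["rate_hz"]),
        )


def _pink_noise(rng: np.random.Generator, n: int, rate_hz: float) -> np.ndarray:
    """Unit-RMS noise with 1/f power spectrum (spectral amplitude f^-1/2)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** -0.5
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n=n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def generate_ssvep_trial(
    intended_target: int,
    duration_s: float,
    snr: float,
    stimulus_set: StimulusSet | None = None,
    rate_hz: float = DEFAULT_EEG_RATE_HZ,
    seed: int | np.random.Generator = 0,
    n_channels: int = len(DEFAULT_CHANNELS),
) -> EEGSegment:
    """Simulate one SSVEP trial while the user attends ``intended_target``.

    Parameters
    ----------
    intended_target
        Index 0-3 of the attended box/LED.
    duration_s
        Trial length in seconds (6 s in calibration).
    snr
        Per-channel RMS(signal)/RMS(noise).  0 gives pure noise; ``np.inf``
        a noise-free trial.
    seed
        Integer seed or an existing Generator; identical arguments (including
        the seed) give bit-identical output.
    """
    stimulus_set = stimulus_set or StimulusSet()
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not 0 <= intended_target < stimulus_set.n_targets:
        raise ValueError(f"unknown target index {intended_target}")
    if snr < 0:
        raise ValueError("snr must be nonnegative")
    if rate_hz <= 2 * stimulus_set.max_harmonic_hz:
        raise ValueError("rate_hz must exceed twice the highest harmonic")
    rng = np.random.default_rng(seed)

    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    freq = stimulus_set.frequencies_hz[intended_target]

    samples = np.empty((n_channels, n))
    for ch in range(n_channels):
        # Channel-specific gains and phases: occipital electrodes see the same
        # response with modest topographic variation.
        sig = np.zeros(n)
        for h in range(1, stimulus_set.n_harmonics + 1):
            amp = HARMONIC_RATIO ** (h - 1) * rng.uniform(0.7, 1.3)
            phase = rng.uniform(0, 2 * np.pi)
            sig += amp * np.sin(2 * np.pi * h * freq * t + phase)
        noise = _pink_noise(rng, n, rate_hz)
        sig_rms = np.sqrt(np.mean(sig**2))
        if np.isinf(snr):
            channel = sig / sig_rms * NOISE_RMS_UV
        elif snr == 0:
            channel = noise * NOISE_RMS_UV
        else:
            channel = (sig / sig_rms * snr + noise) * NOISE_RMS_UV
        samples[ch] = channel
    return EEGSegment(samples=samples, rate_hz=rate_hz,
                      channel_labels=tuple(f"ch{c}" for c in range(n_channels))
                      if n_channels != len(DEFAULT_CHANNELS) else DEFAULT_CHANNELS)


def generate_gaze_trial(
    intended_target: int,
    duration_s: float,
    scatter_deg: float,
    dropout_rate: float = 0.0,
    layout: ScreenLayout | None = None,
    rate_hz: float = DEFAULT_GAZE_RATE_HZ,
    seed: int | np.random.Generator = 0,
) -> GazeTrail:
    """Simulate one eye-tracking trial fixating ``intended_target``.

    Points are drawn i.i.d. from an isotropic bivariate normal centered on the
    target; a Bernoulli(``dropout_rate``) subset is marked invalid (tracker
    dropout).
    """
    layout = layout or ScreenLayout()
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not 0 <= intended_target < len(layout.boxes):
        raise ValueError(f"unknown target index {intended_target}")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    if scatter_deg < 0:
        raise ValueError("scatter_deg must be nonnegative")
    rng = np.random.default_rng(seed)

    n = int(round(duration_s * rate_hz))
    timestamps = (np.arange(n) + 1) / rate_hz
    center = np.asarray(layout.boxes[intended_target].center)
    points = center + scatter_deg * rng.standard_normal((n, 2))
    validity = rng.random(n) >= dropout_rate
    return GazeTrail(timestamps=timestamps, points=points, validity=validity,
                     rate_hz=rate_hz)


def inject_artifacts(
    segment: EEGSegment,
    burst_rate: float,
    amplitude_factor: float = 50.0,
    seed: int | np.random.Generator = 0,
    burst_duration_s: float = 0.25,
) -> EEGSegment:
    """Add intermittent high-amplitude non-EEG bursts to random channels.

    Burst onsets follow a Poisson process at ``burst_rate`` events/minute over
    the segment; each burst contaminates one random channel with a Hann-
    windowed transient whose peak is ``amplitude_factor`` times the channel's
    pre-injection peak.  Affected channels get their ``quality_flags`` set.
    ``burst_rate = 0`` returns the input unchanged.
    """
    if burst_rate < 0:
        raise ValueError("burst_rate must be nonnegative")
    if burst_rate == 0:
        return segment
    rng = np.random.default_rng(seed)

    samples = segment.samples.copy()
    flags = segment.quality_flags.copy()
    n_events = rng.poisson(burst_rate * segment.duration_s / 60.0)
    # Odd width so the Hann window attains exactly 1.0 at its center sample.
    width = max(3, int(round(burst_duration_s * segment.rate_hz)) | 1)
    if width > segment.n_samples:
        width = max(1, (segment.n_samples - 1) | 1)
    window = np.hanning(width)
    for _ in range(n_events):
        ch = int(rng.integers(segment.n_channels))
        start = int(rng.integers(0, max(1, segment.n_samples - width)))
        peak = np.max(np.abs(segment.samples[ch])) or 1.0
        # Align the burst's sign with the underlying sample so the contaminated
        # peak is guaranteed >= amplitude_factor x the pre-injection peak.
        center_val = samples[ch, start + width // 2]
        sign = 1.0 if center_val >= 0 else -1.0
        samples[ch, start : start + width] += sign * amplitude_factor * peak * window
        flags[ch] = True
    return replace(segment, samples=samples, quality_flags=flags)
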