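"""Seeded generator of EEG-like 4-class datasets.

The generator emulates the *structure* the classifier pipeline assumes —
19 channels at 500 Hz, labeled 1-second segments, four classes with
configurable counts — not physiological EEG.  Because the pipeline only
ever sees four moments per channel, each class is built to leave a
distinct signature in those moments on top of a shared stationary AR(2)
background:

* class 0 (normal): AR(2) background noise only;
* class 1 (complex partial): high-amplitude ~3 Hz spike-wave bursts —
  raised standard deviation and strongly positive excess kurtosis;
* class 2 (electrographic): sustained 7 Hz rhythm — raised standard
  deviation with *negative* excess kurtosis (a sinusoid scores -1.5);
* class 3 (video-detected): slow baseline drift — shifted mean.

Per-channel gains spread the signature across the montage the way a
scalp field would differ between electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .edf import write_edf
from .features import CHANNELS_19, EEGSegment

__all__ = ["SyntheticConfig", "generate_dataset", "export_edf", "load_labels_csv"]

#: per-class segment counts of the real recordings this emulates
DEFAULT_COUNTS = (3895, 3034, 705, 111)


@dataclass
class SyntheticConfig:
    """Knobs of the generative model (amplitudes in microvolts)."""

    n_per_class: tuple[int, int, int, int] = DEFAULT_COUNTS
    n_channels: int = 19
    fs: float = 500.0
    seed: int = 0
    ar_coeffs: tuple[float, float] = (0.5, -0.25)
    noise_scale: float = 10.0
    spike_rate: float = 3.0          # class 1 burst rate, events/s
    spike_amplitude: float = 120.0   # class 1 spike height
    spike_width: float = 0.02        # class 1 spike half-width, seconds
    osc_freq: float = 7.0            # class 2 rhythm, Hz
    osc_amplitude: float = 30.0      # class 2 rhythm amplitude
    drift_amplitude: float = 40.0    # class 3 baseline shift
    channel_gain_spread: float = 0.2

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("segment counts must be nonnegative")
        if self.fs <= 0 or self.n_channels <= 0:
            raise ValueError("fs and n_channels must be positive")
        a1, a2 = self.ar_coeffs
        roots = np.roots([1.0, -a1, -a2])
        if np.any(np.abs(roots) >= 1.0):
            raise ValueError("AR(2) coefficients must be stationary")
        if not 0 <= self.channel_gain_spread < 1:
            raise ValueError("channel_gain_spread must lie in [0, 1)")


def _background(cfg: SyntheticConfig, rng: np.random.Generator,
                n_samples: int) -> np.ndarray:
    """Stationary AR(2) noise per channel (vectorized filter, burn-in 100)."""
    burn = 100
    a1, a2 = cfg.ar_coeffs
    eps = rng.normal(0.0, cfg.noise_scale, (cfg.n_channels, n_samples + burn))
    x = lfilter([1.0], [1.0, -a1, -a2], eps, axis=1)
    return x[:, burn:]


def _class_component(cfg: SyntheticConfig, rng: np.random.Generator,
                     label: int, n_samples: int) -> np.ndarray:
    t = np.arange(n_samples) / cfg.fs
    if label == 0:
        return np.zeros(n_samples)
    if label == 1:
        # jittered spike train with a slow wave after each spike
        comp = np.zeros(n_samples)
        period = cfg.fs / cfg.spike_rate
        width = max(cfg.spike_width * cfg.fs, 1.0)
        centers = np.arange(period / 2, n_samples, period)
        centers = centers + rng.uniform(-0.1, 0.1, centers.size) * period
        idx = np.arange(n_samples)
        for c in centers:
            comp += cfg.spike_amplitude * np.exp(-0.5 * ((idx - c) / width) ** 2)
            comp += 0.3 * cfg.spike_amplitude * np.exp(
                -0.5 * ((idx - c - 3 * width) / (3 * width)) ** 2)
        return comp
    if label == 2:
        phase = rng.uniform(0, 2 * np.pi)
        return cfg.osc_amplitude * np.sin(2 * np.pi * cfg.osc_freq * t + phase)
    if label == 3:
        level = cfg.drift_amplitude * rng.uniform(0.8, 1.5)
        # slow drift: DC level plus a fraction of a 0.5 Hz cycle
        return level * (1.0 + 0.25 * np.sin(2 * np.pi * 0.5 * t
                                            + rng.uniform(0, 2 * np.pi)))
    raise ValueError(f"unknown class label {label}")


def generate_dataset(cfg: SyntheticConfig | None = None) -> list[EEGSegment]:
    """All segments, grouped by class; bitwise-reproducible per seed."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.fs))
    names = (list(CHANNELS_19) if cfg.n_channels == 19
             else [f"ch{i}" for i in range(cfg.n_channels)])
    segments: list[EEGSegment] = []
    t_index = 0
    for label, count in enumerate(cfg.n_per_class):
        for _ in range(count):
            bg = _background(cfg, rng, n_samples)
            comp = _class_component(cfg, rng, label, n_samples)
            gains = rng.uniform(1 - cfg.channel_gain_spread,
                                1 + cfg.channel_gain_spread, cfg.n_channels)
            data = bg + gains[:, None] * comp
            segments.append(EEGSegment(
                data=data, label=label, subject_id="sim",
                t_start=float(t_index), fs=cfg.fs, channel_names=names,
            ))
            t_index += 1
    return segments


def export_edf(segments: list[EEGSegment], edf_path, labels_path=None) -> None:
    """Concatenate segments into one EDF recording (+ labels CSV)."""
    if not segments:
        raise ValueError("no segments to export")
    names = segments[0].channel_names
    fs = segments[0].fs
    data = np.concatenate([s.data for s in segments], axis=1)
    write_edf(edf_path, data, fs, names)
    if labels_path is not None:
        pd.DataFrame({
            "subject_id": [s.subject_id for s in segments],
            "t_start": np.arange(len(segments), dtype=float),
            "label": [s.label for s in segments],
        }).to_csv(labels_path, index=False)


def load_labels_csv(path) -> np.ndarray:
    return pd.read_csv(path)["label"].to_numpy(dtype=int)
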