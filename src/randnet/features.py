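"""EEG segmentation and statistical feature extraction.

Recordings are cut into contiguous, non-overlapping 1-second windows
(19 channels x 500 samples by default) and each window is summarized by
four moments per channel — standard deviation, excess kurtosis, skewness
and mean — giving the 76-dimensional vectors the classifier consumes.
Features are min-max scaled to [0, 1] with parameters fitted on training
data only.

Conventions: std is the population standard deviation (ddof 0); kurtosis
is Fisher excess (a Gaussian scores 0), bias-uncorrected, as is skewness;
a constant channel scores 0 for std, skewness and kurtosis.  The feature
order is channel-major: ``[std, kurtosis, skewness, mean]`` per channel.
Trained weights depend on this order, so it is fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CHANNELS_21",
    "CHANNELS_19",
    "STAT_NAMES",
    "EEGSegment",
    "FeatureVector",
    "NormalizationParams",
    "segment_recording",
    "drop_channels",
    "extract_features",
    "feature_matrix",
    "fit_normalizer",
    "apply_normalizer",
    "features_to_dataframe",
    "save_features_csv",
    "load_features_csv",
]

#: 10-20 montage as recorded (21 electrodes incl. ear references)
CHANNELS_21 = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz", "A1", "A2",
]
#: uniform layout after dropping Cz and Pz
CHANNELS_19 = [c for c in CHANNELS_21 if c not in ("Cz", "Pz")]

STAT_NAMES = ("std", "kurtosis", "skewness", "mean")


@dataclass
class EEGSegment:
    """One window of multichannel signal (channels x samples, microvolts)."""

    data: np.ndarray
    label: int
    subject_id: str = ""
    t_start: float = 0.0
    fs: float = 500.0
    channel_names: list[str] = field(default_factory=lambda: list(CHANNELS_19))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("segment data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel name count must match row count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class FeatureVector:
    """Ordered per-channel statistics with label and provenance."""

    values: np.ndarray
    label: int
    subject_id: str = ""
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


def segment_recording(
    signal: np.ndarray,
    fs: float,
    labels,
    window_seconds: float = 1.0,
    subject_id: str = "",
    channel_names: list[str] | None = None,
    expected_channels: int | None = None,
) -> list[EEGSegment]:
    """Cut a recording into labeled, contiguous windows.

    The trailing partial window is discarded; window *i* receives
    ``labels[i]``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2:
        raise ValueError("signal must be channels x samples")
    n_ch, n_samp = signal.shape
    if expected_channels is not None and n_ch != expected_channels:
        raise ValueError(
            f"expected {expected_channels} channels, got {n_ch}"
        )
    if channel_names is None:
        channel_names = (list(CHANNELS_19) if n_ch == 19
                         else [f"ch{i}" for i in range(n_ch)])
    win = int(round(fs * window_seconds))
    n_win = n_samp // win
    labels = list(labels)
    if len(labels) < n_win:
        raise ValueError(
            f"{n_win} windows but only {len(labels)} labels provided"
        )
    return [
        EEGSegment(
            data=signal[:, i * win:(i + 1) * win],
            label=int(labels[i]),
            subject_id=subject_id,
            t_start=i * window_seconds,
            fs=fs,
            channel_names=channel_names,
        )
        for i in range(n_win)
    ]


def drop_channels(
    signal: np.ndarray,
    channel_names: list[str],
    names: tuple[str, ...] = ("Cz", "Pz"),
) -> tuple[np.ndarray, list[str]]:
    """Remove named channels (order of the rest preserved).

    Some records already lack the channels being dropped; those names are
    skipped with a warning so heterogeneous records map onto one layout.
    """
    signal = np.asarray(signal)
    if signal.shape[0] != len(channel_names):
        raise ValueError("channel_names must match signal rows")
    missing = [n for n in names if n not in channel_names]
    if missing:
        warnings.warn(f"channels not present, skipped: {missing}", stacklevel=2)
    keep = [i for i, n in enumerate(channel_names) if n not in names]
    return signal[keep], [channel_names[i] for i in keep]


def _channel_stats(x: np.ndarray) -> tuple[float, float, float, float]:
    mean = float(np.mean(x))
    std = float(np.std(x))  # population, ddof 0
    if std == 0.0:
        return 0.0, 0.0, 0.0, mean  # degenerate: flat channel
    kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    skew = float(stats.skew(x, bias=True))
    return std, kurt, skew, mean


def extract_features(segment: EEGSegment) -> FeatureVector:
    """Four moments per channel, channel-major order ``[std, kurt, skew, mean]``."""
    data = segment.data
    if np.any(~np.isfinite(data)):
        bad = int(np.nonzero(~np.isfinite(data).all(axis=1))[0][0])
        name = segment.channel_names[bad]
        raise ValueError(f"non-finite samples in channel {name!r}")
    values = np.empty(4 * segment.n_channels)
    for c in range(segment.n_channels):
        values[4 * c:4 * c + 4] = _channel_stats(data[c])
    return FeatureVector(
        values=values,
        label=segment.label,
        subject_id=segment.subject_id,
        t_start=segment.t_start,
    )


def feature_matrix(segments: list[EEGSegment]) -> tuple[np.ndarray, np.ndarray]:
    """Stack extracted features: (X, y)."""
    vecs = [extract_features(s) for s in segments]
    X = np.vstack([v.values for v in vecs])
    y = np.array([v.label for v in vecs], dtype=int)
    return X, y


@dataclass
class NormalizationParams:
    """Per-feature min-max scaling, X' = (X - x_min) / (x_max - x_min).

    Fitted on training data only; transformed values are clipped to
    [0, 1], and a constant feature maps to 0.
    """

    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if np.any(self.x_max < self.x_min):
            raise ValueError("x_max must be >= x_min elementwise")

    @classmethod
    def fit(cls, X: np.ndarray) -> "NormalizationParams":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size == 0:
            raise ValueError("cannot fit a normalizer on empty data")
        return cls(x_min=X.min(axis=0), x_max=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.x_max - self.x_min
        safe = np.where(span > 0, span, 1.0)
        out = (X - self.x_min) / safe
        out = np.where(span > 0, out, 0.0)
        return np.clip(out, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"x_min": self.x_min.tolist(), "x_max": self.x_max.tolist()}

    @classmethod
    def from_dict(cls, payload: dict) -> "NormalizationParams":
        return cls(np.asarray(payload["x_min"], dtype=float),
                   np.asarray(payload["x_max"], dtype=float))


def fit_normalizer(train: np.ndarray | list[FeatureVector]) -> NormalizationParams:
    if isinstance(train, list):
        train = np.vstack([v.values for v in train])
    return NormalizationParams.fit(train)


def apply_normalizer(params: NormalizationParams, v):
    if params is None:
        raise ValueError("normalizer must be fitted before use")
    if isinstance(v, FeatureVector):
        return FeatureVector(params.transform(v.values), v.label,
                             v.subject_id, v.t_start)
    return params.transform(v)


# ---------------------------------------------------------------------------
# tabular persistence: one row per segment

def _feature_columns(n_channels: int, channel_names=None) -> list[str]:
    if channel_names is None:
        channel_names = (CHANNELS_19 if n_channels == 19
                         else [f"ch{i}" for i in range(n_channels)])
    return [f"{ch}_{st}" for ch in channel_names for st in STAT_NAMES]


def features_to_dataframe(
    segments: list[EEGSegment],
) -> pd.DataFrame:
    vecs = [extract_features(s) for s in segments]
    n_channels = segments[0].n_channels
    cols = _feature_columns(n_channels, segments[0].channel_names)
    df = pd.DataFrame([v.values for v in vecs], columns=cols)
    df.insert(0, "label", [v.label for v in vecs])
    df.insert(0, "t_start", [v.t_start for v in vecs])
    df.insert(0, "subject_id", [v.subject_id for v in vecs])
    return df


def save_features_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
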