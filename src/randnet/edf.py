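"""Minimal EDF (European Data Format) writing and mne-backed reading.

EDF stores an ASCII header plus 16-bit little-endian samples, one data
record at a time.  Writing is implemented here directly against the
format layout (fixed-width ASCII fields; per-channel physical/digital
calibration); reading goes through :mod:`mne`, which also serves as an
independent check that the writer emits standard-conforming files.

Samples are quantized to the 16-bit digital range per channel, so a
round trip reproduces the signal only up to one quantization step
``(phys_max - phys_min) / 65535``.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["write_edf", "read_edf", "quantization_step"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ASCII characters")
    return s.ljust(width).encode("ascii")


def _phys_bounds(x: np.ndarray) -> tuple[float, float]:
    lo = math.floor(float(x.min()))
    hi = math.ceil(float(x.max()))
    if hi <= lo:
        hi = lo + 1
    return lo, hi


def quantization_step(phys_min: float, phys_max: float) -> float:
    return (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)


def write_edf(
    path,
    data: np.ndarray,
    fs: float,
    channel_names: list[str],
    physical_dimension: str = "uV",
    patient_id: str = "X",
    recording_id: str = "randnet",
) -> None:
    """Write ``data`` (channels x samples, physical units) as EDF.

    Each data record holds one second; trailing samples that do not fill
    a whole record are dropped, mirroring the 1-s segmentation the rest
    of the pipeline uses.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("one channel name per row required")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = n_samp // spr
    if n_rec == 0:
        raise ValueError("need at least one full second of data")

    bounds = [_phys_bounds(data[c]) for c in range(n_ch)]
    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (n_ch + 1)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    per_signal = b"".join([
        b"".join(_field(name, 16) for name in channel_names),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(physical_dimension, 8) for _ in range(n_ch)),
        b"".join(_field(f"{lo:g}", 8) for lo, _ in bounds),
        b"".join(_field(f"{hi:g}", 8) for _, hi in bounds),
        b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch)),
        b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(str(spr), 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ])

    digital = np.empty((n_ch, n_rec * spr), dtype=np.int16)
    for c in range(n_ch):
        lo, hi = bounds[c]
        scaled = (data[c, :n_rec * spr] - lo) / (hi - lo)
        dig = np.rint(scaled * (_DIG_MAX - _DIG_MIN) + _DIG_MIN)
        digital[c] = np.clip(dig, _DIG_MIN, _DIG_MAX).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for rec in range(n_rec):
            block = digital[:, rec * spr:(rec + 1) * spr]
            fh.write(block.astype("<i2").tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (channels x samples in uV, fs, names)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne yields volts for EEG channels
    return data, float(raw.info["sfreq"]), list(raw.ch_names)
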