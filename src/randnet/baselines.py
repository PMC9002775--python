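"""Comparison-model scaffolding.

* an exact convolutional-network shape/parameter calculator (pure integer
  arithmetic, no deep-learning framework) for the reference architecture:
  three valid-padding stride-1 Conv2D layers (32@8x8, 64@5x5, 64@3x3) with
  dropout, a flatten, a 32-unit dense layer and a 4-way output;
* the channel-attention and cosine-transform operators used by residual
  feature extractors: ``att = sigmoid(fc(gap(X)))`` rescaling each channel,
  and a DCT-II/DCT-III pair (orthonormal by default so the round trip is
  exact; the raw unnormalized forward sum is kept available);
* a residual block with ``h(x) = f(x) - x`` semantics (the block learns the
  residual; its output is ``x + f(x)``), stackable to a configurable,
  desk-scale depth;
* a thin adapter that trains an extremely-randomized-trees classifier
  (via scikit-learn) on feature data and emits the same evaluation report
  as the RNN path.  Trainable CNN/ResNet baselines require a deep-learning
  backend and raise an informative error when requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct as _dct, dctn as _dctn, idctn as _idctn

from . import evaluation

__all__ = [
    "LayerSpec",
    "TABLE_CNN_LAYERS",
    "cnn_summary",
    "total_parameters",
    "gap_channel_attention",
    "dct_forward",
    "dct_inverse",
    "dct2_forward",
    "dct2_inverse",
    "residual_stack",
    "train_baseline",
    "BackendUnavailableError",
]


class BackendUnavailableError(RuntimeError):
    """A baseline needs an optional backend that is not installed."""


@dataclass
class LayerSpec:
    """One layer of a sequential convolutional classifier."""

    kind: str                      # conv2d | dropout | flatten | dense
    filters: int = 0
    kernel: tuple[int, int] = (1, 1)
    units: int = 0
    rate: float = 0.0              # dropout rate (documentation only)

    def __post_init__(self) -> None:
        if self.kind not in ("conv2d", "dropout", "flatten", "dense"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv2d" and (self.filters <= 0 or
                                      min(self.kernel) <= 0):
            raise ValueError("conv2d needs positive filters and kernel")
        if self.kind == "dense" and self.units <= 0:
            raise ValueError("dense needs positive units")


#: reference architecture on 19 x 500 x 1 inputs
TABLE_CNN_LAYERS = [
    LayerSpec("conv2d", filters=32, kernel=(8, 8)),
    LayerSpec("dropout", rate=0.25),
    LayerSpec("conv2d", filters=64, kernel=(5, 5)),
    LayerSpec("dropout", rate=0.25),
    LayerSpec("conv2d", filters=64, kernel=(3, 3)),
    LayerSpec("dropout", rate=0.25),
    LayerSpec("flatten"),
    LayerSpec("dense", units=32),
    LayerSpec("dropout", rate=0.5),
    LayerSpec("dense", units=4),
]


def cnn_summary(
    input_shape: tuple[int, int, int] = (19, 500, 1),
    layers: list[LayerSpec] | None = None,
) -> list[dict]:
    """Per-layer output shapes and parameter counts.

    Convolutions are valid-padding, stride 1, with bias:
    ``out = in - kernel + 1`` per spatial axis and
    ``params = kh * kw * c_in * filters + filters``.  Dense layers hold
    ``in * units + units`` parameters; dropout and flatten hold none.
    """
    layers = TABLE_CNN_LAYERS if layers is None else layers
    shape = tuple(int(s) for s in input_shape)
    rows = []
    for spec in layers:
        if spec.kind == "conv2d":
            if len(shape) != 3:
                raise ValueError("conv2d requires an unflattened 3-D input")
            h, w, c = shape
            kh, kw = spec.kernel
            if kh > h or kw > w:
                raise ValueError(
                    f"kernel {spec.kernel} larger than input {h}x{w}")
            shape = (h - kh + 1, w - kw + 1, spec.filters)
            params = kh * kw * c * spec.filters + spec.filters
        elif spec.kind == "dropout":
            params = 0
        elif spec.kind == "flatten":
            shape = (int(np.prod(shape)),)
            params = 0
        else:  # dense
            if len(shape) != 1:
                raise ValueError("dense requires a flattened input")
            params = shape[0] * spec.units + spec.units
            shape = (spec.units,)
        rows.append({"layer": spec.kind, "output_shape": shape,
                     "parameters": params})
    return rows


def total_parameters(rows: list[dict]) -> int:
    return int(sum(r["parameters"] for r in rows))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def gap_channel_attention(
    X: np.ndarray, fc_weights: np.ndarray, fc_bias: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Global-average-pooling channel attention.

    ``att = sigmoid(fc(gap(X)))`` with ``gap`` the per-channel spatial
    mean; channel *i* of the output is ``att_i * X[i]``.  Returns
    ``(att, rescaled)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("X must be channels x height x width")
    c = X.shape[0]
    fc_weights = np.asarray(fc_weights, dtype=float)
    if fc_weights.shape != (c, c):
        raise ValueError(f"fc must map {c} channels to {c} channels")
    gap = X.mean(axis=(1, 2))
    z = fc_weights @ gap
    if fc_bias is not None:
        z = z + np.asarray(fc_bias, dtype=float)
    att = _sigmoid(z)
    return att, att[:, None, None] * X


def dct_forward(x: np.ndarray, norm: str = "ortho") -> np.ndarray:
    """Type-II cosine transform of a 1-D signal.

    ``norm="ortho"`` gives the orthonormal convention (exact inverse);
    ``norm="raw"`` gives the plain sum
    ``f_k = sum_i x_i cos(pi k (i + 1/2) / L)``.
    """
    x = np.asarray(x, dtype=float)
    if norm == "ortho":
        return _dct(x, type=2, norm="ortho")
    if norm == "raw":
        return 0.5 * _dct(x, type=2, norm=None)
    raise ValueError("norm must be 'ortho' or 'raw'")


def dct_inverse(f: np.ndarray) -> np.ndarray:
    """Orthonormal type-III transform: the exact inverse of the forward."""
    return _dct(np.asarray(f, dtype=float), type=3, norm="ortho")


def dct2_forward(x: np.ndarray) -> np.ndarray:
    """Separable orthonormal 2-D DCT-II."""
    return _dctn(np.asarray(x, dtype=float), type=2, norm="ortho")


def dct2_inverse(f: np.ndarray) -> np.ndarray:
    """Separable orthonormal 2-D inverse (DCT-III), matching the 2-D
    cosine-sum reconstruction up to the orthonormal scaling."""
    return _idctn(np.asarray(f, dtype=float), type=2, norm="ortho")


def residual_stack(
    X: np.ndarray, depth: int = 18, seed: int = 0
) -> np.ndarray:
    """Desk-scale stack of residual channel-attention blocks.

    Each block computes a residual ``f(x)`` (channel attention with a
    seeded fully-connected map) and outputs ``x + f(x)``; identity
    initialization keeps the map stable at any depth.
    """
    X = np.asarray(X, dtype=float)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    c = X.shape[0]
    out = X
    for _ in range(depth):
        fc = rng.normal(0.0, 0.1 / c, (c, c))
        att, scaled = gap_channel_attention(out, fc)
        out = out + (scaled - out) / depth  # small residual step per block
    return out


def train_baseline(
    kind: str,
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    train_fraction: float = 0.9,
    n_estimators: int = 100,
    **_ignored,
):
    """Fit a comparison model and evaluate it on a held-out split.

    ``kind="ert"`` trains extremely randomized trees (scikit-learn
    ExtraTreesClassifier) on featurized data.  ``"cnn"`` and ``"resnet"``
    require a deep-learning backend and raise
    :class:`BackendUnavailableError`.
    """
    valid = ("ert", "cnn", "resnet")
    if kind not in valid:
        raise ValueError(f"unknown baseline {kind!r}; valid kinds: {valid}")
    if kind in ("cnn", "resnet"):
        raise BackendUnavailableError(
            f"the trainable {kind!r} baseline needs a deep-learning backend "
            "(e.g. tensorflow or torch), which this installation does not "
            "provide; use cnn_summary/residual_stack for the architecture "
            "calculations, or kind='ert'"
        )
    from sklearn.ensemble import ExtraTreesClassifier

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    tr, te = evaluation.split_train_test(X.shape[0], train_fraction, seed=seed)
    model = ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed)
    model.fit(X[tr], y[tr])
    pred = model.predict(X[te])
    cm = evaluation.confusion(y[te], pred, n_classes=int(y.max()) + 1)
    report = evaluation.metrics(cm, split_info={
        "kind": kind, "seed": seed, "train_fraction": train_fraction,
        "n_train": int(tr.size), "n_test": int(te.size),
    })
    return model, report
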