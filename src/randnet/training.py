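"""Gradient-descent training for the RNN classifier, statsmodels-style.

``RandomNetClassifier`` is the model object (built from a feature matrix
and labels, or a DataFrame); ``.fit()`` runs projected gradient descent on
the nonnegative excitatory/inhibitory weights and returns a
``RandomNetResults`` carrying the trained network, the loss curve, the
fitted min-max normalizer and evaluation helpers.  The functional core
``train_gradient_descent`` is also exposed directly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import evaluation
from .features import NormalizationParams
from .gradient import (
    Weights,
    forward_layers,
    loss_and_gradients,
    numerical_gradients,
    sse_loss,
)
from .network import RandomNeuralNetwork, build_feedforward

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "train_gradient_descent",
    "RandomNetClassifier",
    "RandomNetResults",
]

DEFAULT_ARCH = (76, 100, 80, 4)


@dataclass
class TrainingConfig:
    """Hyperparameters of projected gradient descent.

    The learning rate default suits min-max-normalized features injected
    at ``input_scale``; ``batch_size=None`` means full batch.  ``gradient``
    selects the analytic backward pass or the (slow) central-difference
    fallback used for verification.
    """

    learning_rate: float = 0.5
    epochs: int = 200
    batch_size: int | None = None
    seed: int = 0
    loss: str = "sse"
    gradient: str = "analytic"
    tol: float = 0.0
    input_scale: float = 0.9
    output_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.gradient not in ("analytic", "numerical"):
            raise ValueError("gradient must be 'analytic' or 'numerical'")
        if self.loss != "sse":
            raise ValueError("only squared-error loss is supported")


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    converged: bool = False
    epochs_run: int = 0


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def _blocks_from_net(net: RandomNeuralNetwork) -> Weights:
    sls = net.layer_slices
    return [
        (net.w_plus[sls[k], sls[k + 1]].copy(), net.w_minus[sls[k], sls[k + 1]].copy())
        for k in range(len(sls) - 1)
    ]


def _net_from_blocks(
    blocks: Weights, layer_sizes: list[int], output_rate: float
) -> RandomNeuralNetwork:
    return build_feedforward(
        layer_sizes, weights=blocks, output_rate=output_rate
    )


def train_gradient_descent(
    features: np.ndarray,
    labels: np.ndarray,
    layer_sizes: tuple[int, ...] = DEFAULT_ARCH,
    cfg: TrainingConfig | None = None,
) -> tuple[RandomNeuralNetwork, TrainingHistory]:
    """Train a feedforward RNN on normalized features (values in [0, 1]).

    Weights are projected onto the nonnegative orthant after every update,
    which keeps the queueing interpretation (rates are nonnegative and the
    conservation identity holds by construction at all times).
    """
    cfg = cfg or TrainingConfig()
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != layer_sizes[0]:
        raise ValueError(
            f"feature matrix must be (n_samples, {layer_sizes[0]})"
        )
    if np.any(X < -1e-9) or np.any(X > 1 + 1e-9):
        raise ValueError("features must be min-max normalized to [0, 1]")
    y = np.asarray(labels, dtype=int)
    targets = _one_hot(y, layer_sizes[-1])
    present = np.bincount(y, minlength=layer_sizes[-1])
    if np.any(present == 0):
        warnings.warn(
            f"classes {np.nonzero(present == 0)[0].tolist()} absent from "
            "training data", stacklevel=2
        )
    lam = cfg.input_scale * X

    net0 = build_feedforward(list(layer_sizes), seed=cfg.seed,
                             output_rate=cfg.output_rate)
    blocks = _blocks_from_net(net0)
    history = TrainingHistory()
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]

    for epoch in range(cfg.epochs):
        if cfg.batch_size is None:
            order = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            order = [perm[i:i + cfg.batch_size]
                     for i in range(0, n, cfg.batch_size)]
        for idx in order:
            if cfg.gradient == "analytic":
                loss, grads = loss_and_gradients(
                    blocks, lam[idx], targets[idx], cfg.output_rate
                )
            else:
                fs = forward_layers(blocks, lam[idx], cfg.output_rate)
                loss = sse_loss(fs[-1], targets[idx])
                grads = numerical_gradients(
                    blocks, lam[idx], targets[idx], cfg.output_rate
                )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            blocks = [
                (np.maximum(wp - cfg.learning_rate * gp, 0.0),
                 np.maximum(wm - cfg.learning_rate * gm, 0.0))
                for (wp, wm), (gp, gm) in zip(blocks, grads)
            ]
        full_loss = sse_loss(
            forward_layers(blocks, lam, cfg.output_rate)[-1], targets
        )
        history.loss.append(full_loss)
        history.epochs_run = epoch + 1
        if cfg.tol > 0 and len(history.loss) > 1:
            if abs(history.loss[-2] - full_loss) < cfg.tol:
                history.converged = True
                break

    net = _net_from_blocks(blocks, list(layer_sizes), cfg.output_rate)
    return net, history


def predict_batch(
    net: RandomNeuralNetwork,
    features: np.ndarray,
    input_scale: float = 0.9,
    output_rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized prediction: labels and output activations for many samples."""
    blocks = _blocks_from_net(net)
    rate = (net.r[net.layer_slices[-1]][0] if output_rate is None else output_rate)
    X = np.atleast_2d(np.asarray(features, dtype=float))
    fs = forward_layers(blocks, input_scale * np.clip(X, 0.0, 1.0), rate)
    out = fs[-1]
    return np.argmax(out, axis=1), out


class RandomNetClassifier:
    """Random-neural-network classifier over statistical EEG features.

    Parameters
    ----------
    features : (n_samples, n_features) array of raw (unnormalized) features.
    labels : integer class labels, ``0..n_classes-1``.
    layer_sizes : network architecture; input width must equal the feature
        count and output width the number of classes (default 76-100-80-4).
    normalize : fit a min-max normalizer on the training features (the
        network injects features as Poisson rates in [0, input_scale]).
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        layer_sizes: tuple[int, ...] = DEFAULT_ARCH,
        normalize: bool = True,
    ) -> None:
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on sample count")
        if self.features.shape[1] != layer_sizes[0]:
            raise ValueError(
                f"architecture expects {layer_sizes[0]} input features, "
                f"got {self.features.shape[1]}"
            )
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        self.normalize = normalize

    @classmethod
    def from_dataframe(
        cls,
        df,
        label_column: str = "label",
        feature_columns: list[str] | None = None,
        **kwargs,
    ) -> "RandomNetClassifier":
        """Build from a DataFrame holding one row per segment."""
        if feature_columns is None:
            skip = {label_column, "subject_id", "t_start"}
            feature_columns = [c for c in df.columns if c not in skip]
        X = df[feature_columns].to_numpy(dtype=float)
        y = df[label_column].to_numpy(dtype=int)
        if "layer_sizes" not in kwargs:
            kwargs["layer_sizes"] = (X.shape[1], 100, 80,
                                     int(y.max()) + 1 if y.size else 4)
        return cls(X, y, **kwargs)

    def fit(self, cfg: TrainingConfig | None = None, **overrides) -> "RandomNetResults":
        cfg = cfg or TrainingConfig(**overrides)
        if self.normalize:
            normalizer = NormalizationParams.fit(self.features)
            X = normalizer.transform(self.features)
        else:
            normalizer = None
            X = self.features
        net, history = train_gradient_descent(
            X, self.labels, self.layer_sizes, cfg
        )
        return RandomNetResults(self, net, normalizer, history, cfg)


class RandomNetResults:
    """Fitted classifier: trained network, normalizer, loss curve, reports."""

    def __init__(
        self,
        model: RandomNetClassifier | None,
        network: RandomNeuralNetwork,
        normalizer: NormalizationParams | None,
        history: TrainingHistory,
        config: TrainingConfig,
    ) -> None:
        self.model = model
        self.network = network
        self.normalizer = normalizer
        self.history = history
        self.config = config

    # -- inference --------------------------------------------------------
    def _normalized(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if self.normalizer is not None:
            X = self.normalizer.transform(X)
        return X

    def predict(self, features: np.ndarray) -> np.ndarray:
        labels, _ = predict_batch(
            self.network, self._normalized(features),
            input_scale=self.config.input_scale,
            output_rate=self.config.output_rate,
        )
        return labels

    def predict_activations(self, features: np.ndarray) -> np.ndarray:
        _, acts = predict_batch(
            self.network, self._normalized(features),
            input_scale=self.config.input_scale,
            output_rate=self.config.output_rate,
        )
        return acts

    def evaluate(self, features: np.ndarray, labels: np.ndarray):
        """Confusion matrix and the full one-vs-rest metric report."""
        pred = self.predict(features)
        cm = evaluation.confusion(np.asarray(labels, dtype=int), pred,
                                  n_classes=self.network.layer_sizes[-1])
        return evaluation.metrics(cm)

    # -- reporting --------------------------------------------------------
    @property
    def final_loss(self) -> float | None:
        return self.history.loss[-1] if self.history.loss else None

    def summary(self) -> str:
        arch = "-".join(str(s) for s in self.network.layer_sizes)
        train_acc = None
        if self.model is not None:
            pred = self.predict(self.model.features)
            train_acc = float(np.mean(pred == self.model.labels))
        lines = [
            "Random Neural Network classifier",
            "=" * 40,
            f"architecture        {arch}",
            f"neurons             {self.network.n_neurons}",
            f"epochs run          {self.history.epochs_run}",
            f"learning rate       {self.config.learning_rate}",
            f"input scale         {self.config.input_scale}",
            f"final loss          "
            f"{'n/a' if self.final_loss is None else f'{self.final_loss:.6f}'}",
        ]
        if train_acc is not None:
            lines.append(f"training accuracy   {train_acc:.4f}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def _payload(self) -> dict:
        return {
            "network": self.network.to_dict(),
            "normalizer": (None if self.normalizer is None
                           else self.normalizer.to_dict()),
            "config": {
                "learning_rate": self.config.learning_rate,
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "seed": self.config.seed,
                "loss": self.config.loss,
                "gradient": self.config.gradient,
                "tol": self.config.tol,
                "input_scale": self.config.input_scale,
                "output_rate": self.config.output_rate,
            },
            "history": {
                "loss": self.history.loss,
                "converged": self.history.converged,
                "epochs_run": self.history.epochs_run,
            },
        }

    def save(self, path) -> None:
        """Serialize to JSON (``.json``) or HDF5 (any other suffix)."""
        path = str(path)
        payload = self._payload()
        if path.endswith(".json"):
            with open(path, "w") as fh:
                json.dump(payload, fh)
        else:
            import h5py

            with h5py.File(path, "w") as fh:
                net = fh.create_group("network")
                for key in ("w_plus", "w_minus", "r", "d"):
                    net.create_dataset(key, data=np.asarray(
                        payload["network"][key]))
                net.attrs["layer_sizes"] = payload["network"]["layer_sizes"]
                if payload["normalizer"] is not None:
                    norm = fh.create_group("normalizer")
                    norm.create_dataset(
                        "x_min", data=np.asarray(payload["normalizer"]["x_min"]))
                    norm.create_dataset(
                        "x_max", data=np.asarray(payload["normalizer"]["x_max"]))
                fh.attrs["config"] = json.dumps(payload["config"])
                fh.attrs["history"] = json.dumps(payload["history"])

    @classmethod
    def load(cls, path) -> "RandomNetResults":
        path = str(path)
        if path.endswith(".json"):
            with open(path) as fh:
                payload = json.load(fh)
        else:
            import h5py

            with h5py.File(path, "r") as fh:
                payload = {
                    "network": {
                        "layer_sizes": [int(s) for s in
                                        fh["network"].attrs["layer_sizes"]],
                        **{k: fh["network"][k][()] for k in
                           ("w_plus", "w_minus", "r", "d")},
                    },
                    "normalizer": (
                        {"x_min": fh["normalizer"]["x_min"][()],
                         "x_max": fh["normalizer"]["x_max"][()]}
                        if "normalizer" in fh else None
                    ),
                    "config": json.loads(fh.attrs["config"]),
                    "history": json.loads(fh.attrs["history"]),
                }
        network = RandomNeuralNetwork.from_dict(payload["network"])
        normalizer = (None if payload["normalizer"] is None
                      else NormalizationParams.from_dict(payload["normalizer"]))
        cfg = TrainingConfig(**payload["config"])
        hist = TrainingHistory(
            loss=list(payload["history"]["loss"]),
            converged=bool(payload["history"]["converged"]),
            epochs_run=int(payload["history"]["epochs_run"]),
        )
        return cls(None, network, normalizer, hist, cfg)
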