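"""Gelenbe random neural network: data model and steady-state solver.

The random neural network (RNN) is a queueing-theoretic neural model.  Each
neuron *l* holds a nonnegative integer potential k_l; excitatory spikes (+1)
and inhibitory spikes (-1, floored at 0) arrive as Poisson streams, and an
excited neuron (k_l > 0) fires at rate r_l, routing its spike to neuron *j*
as excitatory with probability p+_{l,j}, as inhibitory with probability
p-_{l,j}, or out of the network with probability d(l).  In steady state the
probability that neuron *l* is excited is

    f_l = lambda+_l / (r_l + lambda-_l),

where lambda+_l = sum_j f_j w+_{j,l} + Lambda+_l and
lambda-_l = sum_j f_j w-_{j,l} + Lambda-_l collect internal traffic
(w+-_{j,l} = r_j p+-_{j,l}) and exogenous arrivals Lambda+-.  Firing rates
are tied to the outgoing weights by

    r_l = (1 - d(l))^-1 sum_j [w+_{l,j} + w-_{l,j}],

which makes the routing probabilities sum to 1 - d(l) exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RandomNeuralNetwork",
    "ExogenousInput",
    "SteadyState",
    "DegenerateNeuronError",
    "firing_rates_from_weights",
    "encode_input",
    "solve_steady_state",
    "build_feedforward",
    "predict",
]

#: activations are capped strictly below 1 (probabilities of a busy queue)
F_CLIP = 1.0 - 1e-9

#: firing rate assigned to sink neurons (d = 1, no outgoing weights), for
#: which the rate/weight relation leaves r free
DEFAULT_OUTPUT_RATE = 1.0


class DegenerateNeuronError(ValueError):
    """A neuron receives traffic but has zero service rate (unstable queue)."""


def firing_rates_from_weights(
    w_plus: np.ndarray, w_minus: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Firing rates r_l = (1 - d_l)^-1 * sum_j (w+_{l,j} + w-_{l,j}).

    Neurons with d = 1 must have no outgoing weight (all their traffic
    leaves the network); their rate is returned as 0 and should be set
    explicitly by the caller if they still serve incoming traffic.
    """
    w_plus = np.asarray(w_plus, dtype=float)
    w_minus = np.asarray(w_minus, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(w_plus < 0) or np.any(w_minus < 0):
        raise ValueError("weights must be nonnegative")
    if np.any((d < 0) | (d > 1)):
        raise ValueError("departure probabilities must lie in [0, 1]")
    out = w_plus.sum(axis=1) + w_minus.sum(axis=1)
    sink = d >= 1.0
    if np.any(sink & (out > 0)):
        bad = int(np.nonzero(sink & (out > 0))[0][0])
        raise ValueError(
            f"neuron {bad} has d=1 but nonzero outgoing weights; "
            "probability conservation cannot hold"
        )
    r = np.zeros_like(out)
    r[~sink] = out[~sink] / (1.0 - d[~sink])
    return r


@dataclass
class RandomNeuralNetwork:
    """Weight matrices, firing rates and departure probabilities.

    ``w_plus[l, j]`` / ``w_minus[l, j]`` are the excitatory / inhibitory
    spike rates from neuron *l* to neuron *j*.  ``layer_sizes`` is set for
    feedforward classifier networks and enables the exact one-pass solver;
    ``None`` marks a general topology.
    """

    w_plus: np.ndarray
    w_minus: np.ndarray
    r: np.ndarray
    d: np.ndarray
    layer_sizes: list[int] | None = None

    def __post_init__(self) -> None:
        self.w_plus = np.asarray(self.w_plus, dtype=float)
        self.w_minus = np.asarray(self.w_minus, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        n = self.n_neurons
        if self.w_plus.shape != (n, n) or self.w_minus.shape != (n, n):
            raise ValueError("weight matrices must be square N x N")
        if self.r.shape != (n,) or self.d.shape != (n,):
            raise ValueError("r and d must be length-N vectors")
        if np.any(self.w_plus < 0) or np.any(self.w_minus < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(self.r < 0):
            raise ValueError("firing rates must be nonnegative")
        if np.any((self.d < 0) | (self.d > 1)):
            raise ValueError("departure probabilities must lie in [0, 1]")
        if self.layer_sizes is not None and sum(self.layer_sizes) != n:
            raise ValueError("layer_sizes must sum to the number of neurons")

    @property
    def n_neurons(self) -> int:
        return self.w_plus.shape[0]

    @property
    def layer_slices(self) -> list[slice]:
        if self.layer_sizes is None:
            raise ValueError("network has no layer structure")
        offs = np.concatenate([[0], np.cumsum(self.layer_sizes)])
        return [slice(int(a), int(b)) for a, b in zip(offs[:-1], offs[1:])]

    # -- routing probabilities p+-_{l,j} = w+-_{l,j} / r_l -----------------
    @property
    def p_plus(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(self.r[:, None] > 0, self.w_plus / self.r[:, None], 0.0)
        return p

    @property
    def p_minus(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(self.r[:, None] > 0, self.w_minus / self.r[:, None], 0.0)
        return p

    def conservation_residual(self) -> np.ndarray:
        """Per-neuron |sum_j(p+ + p-) + d - 1| for neurons with r > 0."""
        tot = self.p_plus.sum(axis=1) + self.p_minus.sum(axis=1) + self.d
        res = np.abs(tot - 1.0)
        res[self.r <= 0] = 0.0
        return res

    def validate(self, tol: float = 1e-9) -> None:
        if np.any(self.conservation_residual() > tol):
            raise ValueError("routing probabilities violate conservation")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "layer_sizes": self.layer_sizes,
            "w_plus": self.w_plus.tolist(),
            "w_minus": self.w_minus.tolist(),
            "r": self.r.tolist(),
            "d": self.d.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RandomNeuralNetwork":
        return cls(
            w_plus=np.array(payload["w_plus"], dtype=float),
            w_minus=np.array(payload["w_minus"], dtype=float),
            r=np.array(payload["r"], dtype=float),
            d=np.array(payload["d"], dtype=float),
            layer_sizes=payload.get("layer_sizes"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "RandomNeuralNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ExogenousInput:
    """External Poisson arrival rates Lambda+ (excitatory), Lambda- (inhibitory)."""

    lambda_plus: np.ndarray
    lambda_minus: np.ndarray

    def __post_init__(self) -> None:
        self.lambda_plus = np.asarray(self.lambda_plus, dtype=float)
        self.lambda_minus = np.asarray(self.lambda_minus, dtype=float)
        if self.lambda_plus.shape != self.lambda_minus.shape:
            raise ValueError("rate vectors must share a shape")
        if np.any(self.lambda_plus < 0) or np.any(self.lambda_minus < 0):
            raise ValueError("arrival rates must be nonnegative")

    @classmethod
    def zeros(cls, n: int) -> "ExogenousInput":
        return cls(np.zeros(n), np.zeros(n))


@dataclass
class SteadyState:
    """Solver output: activations f in [0, 1), residual and convergence info."""

    f: np.ndarray
    residual: float
    converged: bool
    iterations: int


def encode_input(
    features: np.ndarray, n_neurons: int, scale: float = 0.9, atol: float = 1e-9
) -> ExogenousInput:
    """Map a normalized feature vector onto input-layer excitatory rates.

    Feature *i* (in [0, 1]) becomes Lambda+_i = scale * feature_i on input
    neuron *i*; every other exogenous rate is zero.
    """
    x = np.asarray(features, dtype=float).ravel()
    if scale <= 0:
        raise ValueError("scale must be positive")
    if np.any(x < -atol) or np.any(x > 1 + atol):
        raise ValueError(
            "features must be normalized to [0, 1] before encoding; "
            "fit and apply a MinMax normalizer first"
        )
    lam = np.zeros(n_neurons)
    lam[: x.size] = scale * np.clip(x, 0.0, 1.0)
    return ExogenousInput(lam, np.zeros(n_neurons))


def _fixed_point_map(
    net: RandomNeuralNetwork, ext: ExogenousInput, f: np.ndarray
) -> np.ndarray:
    lam_plus = f @ net.w_plus + ext.lambda_plus
    lam_minus = f @ net.w_minus + ext.lambda_minus
    den = net.r + lam_minus
    out = np.zeros_like(f)
    zero_den = den <= 0
    if np.any(zero_den & (lam_plus > 0)):
        bad = int(np.nonzero(zero_den & (lam_plus > 0))[0][0])
        raise DegenerateNeuronError(
            f"neuron {bad} receives excitatory traffic but has zero "
            "service rate r + lambda-; its queue is unstable"
        )
    ok = ~zero_den
    out[ok] = np.minimum(lam_plus[ok] / den[ok], F_CLIP)
    return out


def solve_steady_state(
    net: RandomNeuralNetwork,
    ext: ExogenousInput,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> SteadyState:
    """Solve f_l = (lambda+_l) / (r_l + lambda-_l) for all neurons.

    Feedforward layered networks are solved exactly in one topological
    pass.  General topologies use damped fixed-point iteration; failure to
    converge is reported on the result, never silently.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = net.n_neurons
    if ext.lambda_plus.shape != (n,):
        raise ValueError("exogenous input size mismatch")

    if net.layer_sizes is not None:
        # one exact pass: layer k activations depend only on layers < k
        f = np.zeros(n)
        for sl in net.layer_slices:
            f_new = _fixed_point_map(net, ext, f)
            f[sl] = f_new[sl]
        residual = float(np.max(np.abs(f - _fixed_point_map(net, ext, f))))
        return SteadyState(f=f, residual=residual, converged=residual <= tol,
                           iterations=len(net.layer_sizes))

    f = np.zeros(n)
    if not net.w_plus.any() and not net.w_minus.any():
        # no internal traffic: the map is constant, one pass is exact
        f = _fixed_point_map(net, ext, f)
        return SteadyState(f=f, residual=0.0, converged=True, iterations=1)
    for it in range(1, max_iter + 1):
        f_new = _fixed_point_map(net, ext, f)
        f_next = damping * f_new + (1.0 - damping) * f
        residual = float(np.max(np.abs(f_next - _fixed_point_map(net, ext, f_next))))
        f = f_next
        if residual <= tol:
            return SteadyState(f=f, residual=residual, converged=True, iterations=it)
    return SteadyState(f=f, residual=residual, converged=False, iterations=max_iter)


def build_feedforward(
    layer_sizes: list[int],
    seed: int | None = None,
    output_rate: float = DEFAULT_OUTPUT_RATE,
    weights: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> RandomNeuralNetwork:
    """Assemble a strictly feedforward RNN from per-layer weight blocks.

    With ``weights=None``, blocks are drawn i.i.d. uniform on
    [0, 1/fan_out] with the given seed, which puts every non-sink firing
    rate near 1.  Departure probabilities are 0 for all but the output
    layer (d = 1: output spikes always leave the network, rate fixed at
    ``output_rate``).
    """
    if len(layer_sizes) < 2:
        raise ValueError("need at least an input and an output layer")
    n = sum(layer_sizes)
    offs = np.concatenate([[0], np.cumsum(layer_sizes)])
    w_plus = np.zeros((n, n))
    w_minus = np.zeros((n, n))
    if weights is None:
        rng = np.random.default_rng(seed)
        weights = []
        for a, b in zip(layer_sizes[:-1], layer_sizes[1:]):
            hi = 1.0 / b
            weights.append((rng.uniform(0, hi, (a, b)), rng.uniform(0, hi, (a, b))))
    for k, (wp, wm) in enumerate(weights):
        sl_from = slice(offs[k], offs[k + 1])
        sl_to = slice(offs[k + 1], offs[k + 2])
        w_plus[sl_from, sl_to] = wp
        w_minus[sl_from, sl_to] = wm
    d = np.zeros(n)
    d[offs[-2]:] = 1.0
    r = firing_rates_from_weights(w_plus, w_minus, d)
    r[offs[-2]:] = output_rate
    return RandomNeuralNetwork(w_plus=w_plus, w_minus=w_minus, r=r, d=d,
                               layer_sizes=list(layer_sizes))


def predict(
    net: RandomNeuralNetwork,
    features: np.ndarray,
    scale: float = 0.9,
) -> tuple[int, np.ndarray]:
    """Classify one normalized feature vector.

    Returns the predicted class (index of the maximal output activation,
    ties broken toward the lowest index) and the output activations.
    """
    if net.layer_sizes is None:
        raise ValueError("predict requires a layered classifier network")
    ext = encode_input(features, net.n_neurons, scale=scale)
    state = solve_steady_state(net, ext)
    if not state.converged:
        raise RuntimeError("steady-state solver did not converge")
    out = state.f[net.layer_slices[-1]]
    return int(np.argmax(out)), out
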