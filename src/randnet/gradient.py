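"""Analytic gradients for feedforward random neural networks.

The steady state of a feedforward RNN is an explicit composition of
rational layer maps, so the loss gradient can be back-propagated exactly.
With layer activations F_k, excitatory/inhibitory blocks Wp_k, Wm_k
(layer k -> k+1) and firing rates r tied to the outgoing weights
(r_l = sum of outgoing w+ and w- for non-output neurons), each weight
enters the loss twice: through the receiving layer's numerator/denominator
and through the *sending* layer's own firing rate.  Both paths are chained
here; neurons pinned at the activation cap contribute zero derivative
(projected dynamics).
"""

from __future__ import annotations

import numpy as np

from .network import F_CLIP, DegenerateNeuronError

__all__ = ["forward_layers", "loss_and_gradients", "numerical_gradients", "sse_loss"]

Weights = list[tuple[np.ndarray, np.ndarray]]


def _rates(weights: Weights) -> list[np.ndarray]:
    """Firing rates per non-output layer (d = 0 there): row sums of w+ + w-."""
    return [wp.sum(axis=1) + wm.sum(axis=1) for wp, wm in weights]


def forward_layers(
    weights: Weights,
    lam_plus: np.ndarray,
    output_rate: float = 1.0,
) -> list[np.ndarray]:
    """Batched steady-state pass.  ``lam_plus`` is (B, n_input).

    Returns the list of activation matrices F_k, each (B, n_k).
    """
    lam_plus = np.atleast_2d(np.asarray(lam_plus, dtype=float))
    rates = _rates(weights)
    r0 = rates[0]
    if np.any((r0 <= 0) & (lam_plus > 0).any(axis=0)):
        raise DegenerateNeuronError(
            "an input neuron receives traffic but has zero firing rate "
            "(all outgoing weights vanished)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(r0 > 0, lam_plus / r0, 0.0)
    fs = [np.minimum(f, F_CLIP)]
    n_layers = len(weights) + 1
    for k in range(1, n_layers):
        wp, wm = weights[k - 1]
        num = fs[-1] @ wp
        den = (rates[k] if k < n_layers - 1 else np.full(wp.shape[1], output_rate))
        den = den + fs[-1] @ wm
        if np.any((den <= 0) & (num > 0)):
            raise DegenerateNeuronError(f"unstable neuron in layer {k}")
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(den > 0, num / den, 0.0)
        fs.append(np.minimum(f, F_CLIP))
    return fs


def sse_loss(f_out: np.ndarray, targets: np.ndarray) -> float:
    """Half mean (over samples) sum-of-squares error against one-hot targets."""
    diff = f_out - targets
    return float(0.5 * np.sum(diff * diff) / f_out.shape[0])


def loss_and_gradients(
    weights: Weights,
    lam_plus: np.ndarray,
    targets: np.ndarray,
    output_rate: float = 1.0,
) -> tuple[float, Weights]:
    """Loss and exact dL/dWp_k, dL/dWm_k for every layer block."""
    lam_plus = np.atleast_2d(np.asarray(lam_plus, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    fs = forward_layers(weights, lam_plus, output_rate)
    rates = _rates(weights)
    n_layers = len(fs)
    batch = lam_plus.shape[0]
    loss = sse_loss(fs[-1], targets)

    grads: Weights = [
        (np.zeros_like(wp), np.zeros_like(wm)) for wp, wm in weights
    ]
    g = (fs[-1] - targets) / batch  # dL/dF_out
    for k in range(n_layers - 1, 0, -1):
        wp, wm = weights[k - 1]
        f_prev, f_k = fs[k - 1], fs[k]
        den = (rates[k] if k < n_layers - 1 else np.full(wp.shape[1], output_rate))
        den = den + f_prev @ wm
        active = f_k < F_CLIP
        a = np.where(active & (den > 0), g, 0.0)
        safe_den = np.where(den > 0, den, 1.0)
        u = a / safe_den              # dL/d(numerator)
        v = -a * f_k / safe_den       # dL/d(denominator)
        gp, gm = grads[k - 1]
        gp += f_prev.T @ u
        gm += f_prev.T @ v
        if k < n_layers - 1:
            # r_k = row sums of layer-k outgoing blocks
            s = v.sum(axis=0)
            gp_next, gm_next = grads[k]
            gp_next += s[:, None]
            gm_next += s[:, None]
        g = u @ wp.T + v @ wm.T
    # input layer: F_0 = Lambda+ / r_0, and r_0 = row sums of block 0
    r0 = rates[0]
    f0 = fs[0]
    active0 = (f0 < F_CLIP) & (r0 > 0)
    safe_r0 = np.where(r0 > 0, r0, 1.0)
    s0 = np.sum(np.where(active0, g, 0.0) * (-f0 / safe_r0), axis=0)
    gp0, gm0 = grads[0]
    gp0 += s0[:, None]
    gm0 += s0[:, None]
    return loss, grads


def numerical_gradients(
    weights: Weights,
    lam_plus: np.ndarray,
    targets: np.ndarray,
    output_rate: float = 1.0,
    eps: float = 1e-6,
) -> Weights:
    """Central-difference gradients; the independent check on the analytic path."""

    def loss_of(ws: Weights) -> float:
        fs = forward_layers(ws, lam_plus, output_rate)
        return sse_loss(fs[-1], np.atleast_2d(targets))

    grads: Weights = []
    for k in range(len(weights)):
        pair = []
        for which in (0, 1):
            w = weights[k][which]
            g = np.zeros_like(w)
            for idx in np.ndindex(w.shape):
                ws_hi = [(wp.copy(), wm.copy()) for wp, wm in weights]
                ws_lo = [(wp.copy(), wm.copy()) for wp, wm in weights]
                ws_hi[k][which][idx] += eps
                ws_lo[k][which][idx] -= eps
                g[idx] = (loss_of(ws_hi) - loss_of(ws_lo)) / (2 * eps)
            pair.append(g)
        grads.append((pair[0], pair[1]))
    return grads
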