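"""Discrete-event simulation of the spiking queueing network.

The simulator is the correctness oracle for the analytic steady-state
solver: it tracks the integer potentials k_l(t) under Poisson exogenous
arrivals and exponential service, using the Gillespie algorithm, and
reports the fraction of *time* each neuron spends excited (k_l > 0).
Standard errors come from batch means (the busy/idle process is
autocorrelated, so naive binomial errors would be wrong).

The event loop is JIT-compiled; small networks run ~10^6 events/second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import ExogenousInput, RandomNeuralNetwork

__all__ = ["SimulationResult", "simulate_network"]


@dataclass
class SimulationResult:
    busy_fraction: np.ndarray
    stderr: np.ndarray
    total_time: float
    n_events: int


@njit(cache=False)
def _gillespie(lam_plus, lam_minus, r, p_plus, p_minus, n_events, n_batches,
               n_burn, seed):
    np.random.seed(seed)
    n = lam_plus.shape[0]
    k = np.zeros(n, dtype=np.int64)
    batch_busy = np.zeros((n_batches, n))
    batch_time = np.zeros(n_batches)
    per_batch = max((n_events - n_burn) // n_batches, 1)
    ext_rate = lam_plus.sum() + lam_minus.sum()
    events_done = 0
    for e in range(n_events):
        total = ext_rate
        for l in range(n):
            if k[l] > 0:
                total += r[l]
        if total <= 0.0:
            break
        dt = -np.log(np.random.random()) / total
        if e >= n_burn:
            b = min((e - n_burn) // per_batch, n_batches - 1)
            batch_time[b] += dt
            for l in range(n):
                if k[l] > 0:
                    batch_busy[b, l] += dt
        # pick the event
        u = np.random.random() * total
        acc = 0.0
        done = False
        for l in range(n):
            acc += lam_plus[l]
            if u < acc:
                k[l] += 1
                done = True
                break
        if not done:
            for l in range(n):
                acc += lam_minus[l]
                if u < acc:
                    if k[l] > 0:
                        k[l] -= 1
                    done = True
                    break
        if not done:
            for l in range(n):
                if k[l] > 0:
                    acc += r[l]
                    if u < acc:
                        # neuron l fires: route the spike
                        k[l] -= 1
                        v = np.random.random()
                        cum = 0.0
                        routed = False
                        for j in range(n):
                            cum += p_plus[l, j]
                            if v < cum:
                                k[j] += 1
                                routed = True
                                break
                        if not routed:
                            for j in range(n):
                                cum += p_minus[l, j]
                                if v < cum:
                                    if k[j] > 0:
                                        k[j] -= 1
                                    routed = True
                                    break
                        # otherwise the spike departs the network (prob d)
                        done = True
                        break
        events_done = e + 1
    return batch_busy, batch_time, events_done


def simulate_network(
    net: RandomNeuralNetwork,
    ext: ExogenousInput,
    n_events: int = 1_000_000,
    seed: int = 0,
    n_batches: int = 40,
    burn_fraction: float = 0.05,
) -> SimulationResult:
    """Empirical busy fractions (and batch-means standard errors).

    The first ``burn_fraction`` of events is discarded as warm-up (the
    chain starts empty, which otherwise biases busy fractions down).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0 <= burn_fraction < 1:
        raise ValueError("burn_fraction must be in [0, 1)")
    batch_busy, batch_time, done = _gillespie(
        np.ascontiguousarray(ext.lambda_plus, dtype=np.float64),
        np.ascontiguousarray(ext.lambda_minus, dtype=np.float64),
        np.ascontiguousarray(net.r, dtype=np.float64),
        np.ascontiguousarray(net.p_plus, dtype=np.float64),
        np.ascontiguousarray(net.p_minus, dtype=np.float64),
        int(n_events),
        int(n_batches),
        int(burn_fraction * n_events),
        int(seed) % (2**32),
    )
    total_time = float(batch_time.sum())
    if total_time == 0.0:
        n = net.n_neurons
        return SimulationResult(np.zeros(n), np.zeros(n), 0.0, int(done))
    busy = batch_busy.sum(axis=0) / total_time
    used = batch_time > 0
    fracs = batch_busy[used] / batch_time[used, None]
    m = int(used.sum())
    stderr = (fracs.std(axis=0, ddof=1) / np.sqrt(m)) if m > 1 else np.full(
        net.n_neurons, np.inf)
    return SimulationResult(busy, stderr, total_time, int(done))
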