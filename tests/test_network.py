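"""Steady-state solver, rate algebra, input encoding and prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import randnet as rn
from randnet.network import DegenerateNeuronError, F_CLIP

from conftest import make_random_feedforward


class TestFiringRates:
    def test_outgoing_sum_no_departure(self):
        w_plus = np.array([[0.0, 2.0], [0.0, 0.0]])
        w_minus = np.array([[0.0, 1.0], [0.0, 0.0]])
        r = rn.firing_rates_from_weights(w_plus, w_minus, np.array([0.0, 1.0]))
        assert r[0] == pytest.approx(3.0)

    def test_departure_probability_inflates_rate(self):
        w_plus = np.array([[0.0, 2.0], [0.0, 0.0]])
        w_minus = np.array([[0.0, 1.0], [0.0, 0.0]])
        r = rn.firing_rates_from_weights(w_plus, w_minus, np.array([0.5, 1.0]))
        assert r[0] == pytest.approx(6.0)

    def test_full_departure_with_outgoing_weights_rejected(self):
        w = np.array([[0.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="d=1"):
            rn.firing_rates_from_weights(w, np.zeros((2, 2)), np.array([1.0, 1.0]))

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_probability_conservation_identity(self, seed):
        """sum_j (p+ + p-) + d = 1 for every neuron with r > 0."""
        gen = np.random.default_rng(seed)
        n = int(gen.integers(2, 8))
        w_plus = gen.uniform(0, 1, (n, n))
        w_minus = gen.uniform(0, 1, (n, n))
        d = gen.uniform(0, 0.9, n)
        r = rn.firing_rates_from_weights(w_plus, w_minus, d)
        net = rn.RandomNeuralNetwork(w_plus, w_minus, r, d)
        assert np.all(net.conservation_residual() < 1e-12)


class TestSolver:
    def test_zero_network_is_silent(self):
        net = rn.build_feedforward([2, 3, 2], seed=0)
        state = rn.solve_steady_state(net, rn.ExogenousInput.zeros(7))
        assert np.all(state.f == 0)
        assert state.converged

    def test_single_neuron_closed_form(self):
        """f = Lambda+/r exactly when there is no inhibition."""
        net = rn.RandomNeuralNetwork(
            np.zeros((1, 1)), np.zeros((1, 1)), np.array([1.0]), np.array([1.0]))
        ext = rn.ExogenousInput(np.array([0.3]), np.zeros(1))
        state = rn.solve_steady_state(net, ext)
        assert state.f[0] == pytest.approx(0.3, abs=1e-12)
        assert state.converged

    def test_fixed_point_residual_on_random_nets(self):
        for seed in range(10):
            net, ext = make_random_feedforward(seed)
            state = rn.solve_steady_state(net, ext, tol=1e-10)
            assert state.converged
            assert state.residual <= 1e-10

    def test_unstable_neuron_raises(self):
        net = rn.RandomNeuralNetwork(
            np.zeros((1, 1)), np.zeros((1, 1)), np.array([0.0]), np.array([1.0]))
        ext = rn.ExogenousInput(np.array([0.5]), np.zeros(1))
        with pytest.raises(DegenerateNeuronError):
            rn.solve_steady_state(net, ext)

    def test_activations_capped_below_one(self):
        net = rn.RandomNeuralNetwork(
            np.zeros((1, 1)), np.zeros((1, 1)), np.array([0.5]), np.array([1.0]))
        ext = rn.ExogenousInput(np.array([2.0]), np.zeros(1))
        state = rn.solve_steady_state(net, ext)
        assert state.f[0] == pytest.approx(F_CLIP)

    def test_monotone_in_exogenous_excitation(self):
        """Raising Lambda+ at an input neuron never lowers its activation."""
        net, ext = make_random_feedforward(3)
        base = rn.solve_steady_state(net, ext).f
        for bump in (0.05, 0.2, 0.5):
            lam = ext.lambda_plus.copy()
            lam[0] += bump
            f = rn.solve_steady_state(
                net, rn.ExogenousInput(lam, ext.lambda_minus)).f
            assert f[0] >= base[0] - 1e-12

    def test_general_topology_iterative_solver(self):
        """A recurrent 2-cycle still satisfies the fixed point."""
        w_plus = np.array([[0.0, 0.3], [0.2, 0.0]])
        w_minus = np.array([[0.0, 0.1], [0.1, 0.0]])
        d = np.zeros(2)
        r = rn.firing_rates_from_weights(w_plus, w_minus, d)
        net = rn.RandomNeuralNetwork(w_plus, w_minus, r, d)  # no layer_sizes
        ext = rn.ExogenousInput(np.array([0.2, 0.1]), np.zeros(2))
        state = rn.solve_steady_state(net, ext, tol=1e-12)
        assert state.converged
        lam_p = state.f @ w_plus + ext.lambda_plus
        lam_m = state.f @ w_minus
        assert np.allclose(state.f, lam_p / (r + lam_m), atol=1e-10)


class TestEncodeInput:
    def test_zero_features_zero_rates(self):
        ext = rn.encode_input(np.zeros(4), 10)
        assert np.all(ext.lambda_plus == 0) and np.all(ext.lambda_minus == 0)

    def test_ones_scale_to_input_layer_only(self):
        ext = rn.encode_input(np.ones(4), 10, scale=0.9)
        assert np.allclose(ext.lambda_plus[:4], 0.9)
        assert np.all(ext.lambda_plus[4:] == 0)

    def test_linearity_in_scale(self, rng):
        x = rng.uniform(0, 1, 6)
        ext = rn.encode_input(x, 12, scale=0.7)
        assert np.allclose(ext.lambda_plus[:6], 0.7 * x)

    def test_unnormalized_features_rejected(self):
        with pytest.raises(ValueError, match="normaliz"):
            rn.encode_input(np.array([1.5, 0.2]), 4)


class TestPredict:
    def _dominant_net(self, favored):
        sizes = [2, 3, 2]
        weights = [
            (np.full((2, 3), 0.2), np.full((2, 3), 0.05)),
            (np.zeros((3, 2)), np.zeros((3, 2))),
        ]
        weights[1][0][:, favored] = 0.5  # excite only the favored output
        return rn.build_feedforward(sizes, weights=weights)

    def test_constructed_dominance(self):
        net = self._dominant_net(favored=1)
        label, acts = rn.predict(net, np.array([0.8, 0.6]))
        assert label == 1
        assert np.all((acts >= 0) & (acts < 1))

    def test_exact_tie_breaks_to_lowest_index(self):
        sizes = [2, 2, 2]
        weights = [
            (np.full((2, 2), 0.3), np.zeros((2, 2))),
            (np.full((2, 2), 0.4), np.zeros((2, 2))),  # symmetric outputs
        ]
        net = rn.build_feedforward(sizes, weights=weights)
        label, acts = rn.predict(net, np.array([0.5, 0.5]))
        assert acts[0] == pytest.approx(acts[1])
        assert label == 0


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        net = rn.build_feedforward([3, 4, 2], seed=9)
        path = tmp_path / "net.json"
        net.to_json(path)
        back = rn.RandomNeuralNetwork.from_json(path)
        assert back.layer_sizes == net.layer_sizes
        assert np.allclose(back.w_plus, net.w_plus)
        assert np.allclose(back.r, net.r)
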