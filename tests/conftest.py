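import numpy as np
import pytest

from randnet.features import feature_matrix
from randnet.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_segments():
    """20 segments per class; enough to exercise every stage quickly."""
    return generate_dataset(SyntheticConfig(n_per_class=(20, 20, 20, 20), seed=1))


@pytest.fixture(scope="session")
def small_features(small_segments):
    return feature_matrix(small_segments)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_random_feedforward(seed, max_neurons=10):
    """Random small layered net with weights in [0, 0.5] and input drive."""
    import randnet as rn

    gen = np.random.default_rng(seed)
    sizes = [int(gen.integers(2, 5)) for _ in range(3)]
    while sum(sizes) > max_neurons:
        sizes = [int(gen.integers(2, 4)) for _ in range(3)]
    weights = [
        (gen.uniform(0, 0.5, (a, b)), gen.uniform(0, 0.5, (a, b)))
        for a, b in zip(sizes[:-1], sizes[1:])
    ]
    net = rn.build_feedforward(sizes, weights=weights)
    lam = np.concatenate([
        gen.uniform(0.1, 0.6, sizes[0]), np.zeros(sum(sizes) - sizes[0])
    ])
    ext = rn.ExogenousInput(lam, np.zeros(sum(sizes)))
    return net, ext


def dual_rail_two_class(n=200, seed=42):
    """Linearly separable 2-feature 2-class set (boundary x0 = x1)."""
    gen = np.random.default_rng(seed)
    y = gen.integers(0, 2, n)
    hi = gen.uniform(0.55, 1.0, n)
    lo = gen.uniform(0.0, 0.35, n)
    X = np.column_stack([np.where(y == 1, hi, lo), np.where(y == 1, lo, hi)])
    return X, y
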