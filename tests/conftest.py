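import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_clouds(n_per_class=20, n_features=10, separation=10.0, seed=0):
    """Two Gaussian clouds separated along the first feature axis."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    b = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    b[:, 0] += separation
    X = np.vstack([a, b])
    labels = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return X, labels


def make_null(n=40, n_features=30, seed=0):
    """Pure-noise features with balanced random labels."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    labels = np.array(["A", "B"] * (n // 2))
    return X, rng.permutation(labels)


@pytest.fixture
def separable():
    return make_clouds()


@pytest.fixture
def null_data():
    return make_null()
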