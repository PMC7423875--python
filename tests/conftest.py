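import numpy as np
import pytest

import sdejs


def random_system(rng, n=None, d=None, c=None, theta=None):
    """A random constrained system K = [A, theta*I], full row rank."""
    n = n or int(rng.integers(3, 11))
    d = d or int(rng.integers(5, 31))
    c = c or int(rng.integers(2, 5))
    theta = theta or float(rng.choice([0.01, 0.1, 1.0]))
    A = rng.standard_normal((n, d))
    Y = rng.standard_normal((n, c))
    K = np.hstack([A, theta * np.eye(n)])
    return sdejs.ConstraintSystem(K=K, Y=Y)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def default_dataset():
    """One realization of the default sparse-classification spec."""
    X, labels, support = sdejs.make_sparse_classification(sdejs.SyntheticSpec(seed=0))
    return X, labels, support


@pytest.fixture(scope="session")
def small_dataset():
    """A small, strongly separable task for fast end-to-end tests."""
    spec = sdejs.SyntheticSpec(
        n_samples=60, n_features=30, n_informative=5, n_classes=2,
        effect_size=2.0, seed=11,
    )
    X, labels, support = sdejs.make_sparse_classification(spec)
    return X, labels, support
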