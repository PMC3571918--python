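import numpy as np
import pytest

from slowfast_plasticity import (make_params, make_pattern_input,
                                 make_sinusoid_input)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pattern_input():
    """Two orthonormal random patterns alternating over a period of 1.2."""
    return make_pattern_input(4, n_patterns=2, durations=(0.7, 0.5), seed=1,
                              orthogonalize=True)


@pytest.fixture(scope="session")
def unit_sinusoid():
    """One-component u(t) = sin(t), period 2*pi."""
    return make_sinusoid_input(1, 2 * np.pi)


@pytest.fixture
def hebbian_params():
    return make_params({"rule": "hebbian", "n": 4, "l": 2.0, "kappa": 5.0,
                        "sigma": 0.1, "mu": 0.8})


@pytest.fixture
def trace_params():
    return make_params({"rule": "trace", "n": 4, "l": 2.0, "kappa": 5.0,
                        "sigma": 0.1, "mu": 0.8, "beta": 3.0})


@pytest.fixture
def stdp_params():
    return make_params({"rule": "stdp", "n": 4, "l": 2.0, "kappa": 5.0,
                        "sigma": 0.1, "mu": 0.8, "gamma": 2.0,
                        "a_plus": 1.0, "a_minus": 0.4})


def random_admissible_W(n, radius, rng, symmetric=True):
    """Random connectivity with spectral radius exactly ``radius``;
    symmetric PSD when requested (the Hebbian/trace invariant set shape)."""
    A = rng.standard_normal((n, n))
    W = A @ A.T if symmetric else A
    return W / np.abs(np.linalg.eigvals(W)).max() * radius
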