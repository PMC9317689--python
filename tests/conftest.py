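import numpy as np
import pytest

from selindex import (
    compute_blues,
    covariance_matrices,
    default_wheat_spec,
    simulate_met,
)


@pytest.fixture(scope="session")
def wheat_spec():
    return default_wheat_spec(seed=11)


@pytest.fixture(scope="session")
def wheat_trial(wheat_spec):
    return simulate_met(wheat_spec)


@pytest.fixture(scope="session")
def wheat_cp(wheat_trial):
    return covariance_matrices(wheat_trial, "combined")


@pytest.fixture(scope="session")
def wheat_blues(wheat_trial):
    return compute_blues(wheat_trial, "combined")


def random_psd_pair(rng, t):
    """Random genetic/phenotypic covariance pair with P - C PSD and P PD."""
    A = rng.standard_normal((t, t))
    C = A @ A.T / t
    B = rng.standard_normal((t, t))
    P = C + B @ B.T / t + 0.05 * np.eye(t)
    return C, P


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
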