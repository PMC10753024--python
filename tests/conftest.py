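import numpy as np
import pytest

from affectdyn import (
    generate_block_sequence,
    make_phenotype,
    reference_matrix,
    simulate_session,
)


@pytest.fixture(scope="session")
def schedule():
    return generate_block_sequence(seed=0)


@pytest.fixture(scope="session")
def high_matrix():
    """Published transition matrix of the high-flexibility participant."""
    return reference_matrix("high")


@pytest.fixture(scope="session")
def low_matrix():
    """Published transition matrix of the low-flexibility participant."""
    return reference_matrix("low")


@pytest.fixture(scope="session")
def high_session():
    """One simulated high-flexibility session, shared across tests."""
    spec = make_phenotype("high", seed=7)
    return spec, simulate_session(spec)


def random_stochastic_matrix(rng: np.random.Generator, strictly_positive=True):
    """A random 4x4 row-stochastic matrix; strictly positive => irreducible."""
    raw = rng.random((4, 4)) + (0.05 if strictly_positive else 0.0)
    return raw / raw.sum(axis=1, keepdims=True)
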