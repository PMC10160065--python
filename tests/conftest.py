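"""Shared fixtures: small canonical models used across the suite."""

import numpy as np
import pytest

from dsbucket.models import HMMParams, SAParams


@pytest.fixture(scope="session")
def binary_eq12() -> HMMParams:
    """The two-state binary model with error rate 0.1 and switch prob 0.2."""
    return HMMParams.symmetric_binary(0.1, 0.2)


@pytest.fixture(scope="session")
def binary_search_model() -> HMMParams:
    """The low-noise binary model used in the end-to-end HMM experiment."""
    return HMMParams.symmetric_binary(0.05, 0.05)


@pytest.fixture(scope="session")
def dna_read_model() -> SAParams:
    """SA model matched to reads with 30% total error, half of it indels."""
    return SAParams.from_error_profile(0.30, 0.5)


@pytest.fixture(scope="session")
def uniform_sa() -> SAParams:
    return SAParams.uniform()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
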