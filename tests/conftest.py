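import numpy as np
import pytest

from connstates import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(n_subjects=8, n_regions=60, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_subject_matrices(n: int, rng: np.random.Generator):
    """Random valid (sc, fc) pair: symmetric, zero diagonal, fc in [-1, 1]."""
    sc = rng.integers(0, 5, size=(n, n)).astype(float)
    sc = np.triu(sc, k=1)
    sc = sc + sc.T
    fc = rng.uniform(-1, 1, size=(n, n))
    fc = np.triu(fc, k=1)
    fc = fc + fc.T
    return sc, fc
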