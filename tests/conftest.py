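import numpy as np
import pytest

from stolsim import reconstruct_cohort
from stolsim.reference import reference_joint_by_score


@pytest.fixture(scope="session")
def ref_cohort():
    """The 401-record cohort rebuilt from the reference tables (no Magnin)."""
    return reconstruct_cohort()


@pytest.fixture(scope="session")
def ref_cohort_magnin():
    """Reconstructed cohort with synthetic Magnin values attached."""
    return reconstruct_cohort(with_magnin=True, seed=20240)


@pytest.fixture(scope="session")
def ref_by_score():
    return reference_joint_by_score()


def random_joint_by_score(rng: np.random.Generator, n_max: int = 60) -> np.ndarray:
    """A random small by-score count matrix (8 x 6) for property tests."""
    return rng.integers(0, 5, size=(8, 6))
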