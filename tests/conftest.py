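import numpy as np
import pytest

from subtypeforge import CohortConfig, ExpressionMatrix, generate_cohort


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        ["fA", "fB"], ["s1", "s2", "s3"],
        np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
        platform="protein", scale_flag="log2",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=7))


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
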