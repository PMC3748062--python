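import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from casehet import AlleleTable, SubclassCounts

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def pooled_table() -> AlleleTable:
    """1000/1000 cohort with case MAF 0.35 and control MAF 0.325."""
    return AlleleTable(700, 1300, 650, 1350)


@pytest.fixture
def enriched_subclass() -> SubclassCounts:
    """200-case subclass at MAF 0.5 hidden inside the pooled cohort."""
    return SubclassCounts(200, 200)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_tables(rng: np.random.Generator, n: int, low: int = 1, high: int = 5000):
    """Random positive integer tables for oracle sweeps."""
    cells = rng.integers(low, high, size=(n, 4))
    return [AlleleTable(*map(float, row)) for row in cells]
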