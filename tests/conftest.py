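import numpy as np
import pytest

from pathent import random_system, table1_systems


@pytest.fixture(scope="session")
def table1():
    """The catalogue of small canonical systems (unit-rate one-pool row)."""
    return table1_systems(lam=1.0)


@pytest.fixture(scope="session")
def random_fixtures():
    """50 seeded random systems of dimension 1-5 for property checks."""
    rng = np.random.default_rng(20260928)
    return [random_system(int(rng.integers(1, 6)), rng=rng) for _ in range(50)]
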