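import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_pvalue_sets(rng):
    """A mix of small random p-value vectors: uniform, spiky, with ties."""
    sets = []
    for _ in range(200):
        n = int(rng.integers(1, 13))
        p = rng.uniform(0.0, 1.0, size=n)
        sets.append(p)
    for _ in range(50):
        n = int(rng.integers(2, 13))
        p = rng.beta(0.3, 4.0, size=n)  # spiky near zero, like real screens
        sets.append(p)
    for _ in range(50):
        n = int(rng.integers(2, 13))
        p = rng.choice([0.01, 0.04, 0.05, 0.2, 0.5, 1.0], size=n)  # ties
        sets.append(p)
    return sets
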