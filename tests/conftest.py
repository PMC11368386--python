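import numpy as np
import pytest

from scdiffuse import FixtureSpec, simulate_counts
from scdiffuse.workflows import prepare


@pytest.fixture(scope="session")
def small_spec():
    """600 cells x 80 genes, two balanced types; cheap enough for unit tests."""
    return FixtureSpec(n_cells=600, n_genes=80,
                       cell_types=[("TypeA", 0.5), ("TypeB", 0.5)], seed=11)


@pytest.fixture(scope="session")
def small_raw(small_spec):
    return simulate_counts(small_spec)


@pytest.fixture(scope="session")
def small_lognorm(small_raw):
    return prepare(small_raw)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
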