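import numpy as np
import pytest

from thermopep.datasets import MESOPHILIC, THERMOPHILIC, load_peptidase_counts


@pytest.fixture(scope="session")
def census():
    """The bundled 23-species catalytic-type count matrix."""
    return load_peptidase_counts()


@pytest.fixture(scope="session")
def census_two_group(census):
    """Mesophilic vs thermophilic rows only (thermotolerant excluded)."""
    return census.subset_groups([MESOPHILIC, THERMOPHILIC])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
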