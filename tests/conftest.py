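import numpy as np
import pytest

from crbnsplice.io_formats import GeneSet, GeneSetCollection, RegulonDB
from crbnsplice.synthetic_data import default_genes


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def genes200():
    return default_genes(200)


@pytest.fixture
def small_regulons():
    return RegulonDB(
        {
            "BATF": frozenset({"IL2RA", "ICAM1", "BMF"}),
            "EZH2": frozenset({"ICAM1", "MT2A"}),
        }
    )


@pytest.fixture
def small_sets():
    return GeneSetCollection(
        [
            GeneSet("S1", "first", ("A", "B", "C")),
            GeneSet("S2", "second", ("C", "D")),
        ]
    )
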