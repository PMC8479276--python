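import numpy as np
import pytest

from tsmda import SyntheticConfig, generate_world
from tsmda.pipeline import PipelineInputs


#: reduced problem size for fast unit/integration tests
TINY = SyntheticConfig(
    n_mirnas=24,
    n_diseases=16,
    n_genes=120,
    n_symptoms=30,
    n_pathways=4,
    edges_per_mirna=8,
    genes_per_disease=10,
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_world():
    return generate_world(TINY)


@pytest.fixture(scope="session")
def tiny_inputs(tiny_world):
    w = tiny_world
    return PipelineInputs(
        w.catalog, w.interactions, w.gene_disease, w.cooccurrence, w.mfs
    )


@pytest.fixture(scope="session")
def default_world():
    """The package's reference synthetic conditions (60 x 40, 5 pathways)."""
    return generate_world(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_inputs(default_world):
    w = default_world
    return PipelineInputs(
        w.catalog, w.interactions, w.gene_disease, w.cooccurrence, w.mfs
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
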