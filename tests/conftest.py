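import numpy as np
import pytest

from orfrate.mrmr import mrmr_rank
from orfrate.pipeline import featurize
from orfrate.simulate import (
    SimulationConfig,
    generate_dataset,
    null_config,
    worked_example_tables,
)

# fixed study conditions used by the heavier end-to-end checks
PLANTED = SimulationConfig(n_orfs=300, seed=0)
NULL = null_config(n_orfs=300, seed=0)


@pytest.fixture(scope="session")
def examples():
    return worked_example_tables()


@pytest.fixture(scope="session")
def small_dataset():
    """A light planted dataset for unit-level pipeline tests."""
    return generate_dataset(SimulationConfig(n_orfs=40, seed=11, n_go_terms=10))


@pytest.fixture(scope="session")
def planted_dataset():
    return generate_dataset(PLANTED)


@pytest.fixture(scope="session")
def planted_features(planted_dataset):
    ds = planted_dataset
    return featurize(ds.records, ds.network, ds.annotations)


@pytest.fixture(scope="session")
def planted_ranking(planted_features, planted_dataset):
    return mrmr_rank(
        planted_features,
        planted_dataset.truth.true_labels,
        top_k=planted_features.n_features,
    )


@pytest.fixture(scope="session")
def null_dataset():
    return generate_dataset(NULL)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
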