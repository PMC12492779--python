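import numpy as np
import pytest

from resurvey.pipeline import preprocess_records
from resurvey.synthetic_data import ScenarioConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small headline-style scenario shared across tests (read-only)."""
    return generate_dataset(ScenarioConfig(n_areas=30, pool_size=200, seed=7))


@pytest.fixture(scope="session")
def small_records(small_dataset):
    """The same dataset after preprocessing to fractional cover."""
    synonym = dict(
        zip(
            small_dataset.synonym_map["observed_name"],
            small_dataset.synonym_map["accepted_name"],
        )
    )
    return preprocess_records(
        small_dataset.plots,
        small_dataset.species_attributes(),
        synonym,
        small_dataset.allometric,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
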