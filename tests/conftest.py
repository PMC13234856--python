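import numpy as np
import pytest

from habitat_radiomics.preprocess import preprocess_study
from habitat_radiomics.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Ten-patient cohort on a 32^3 grid, shared across tests (read-only)."""
    config = SyntheticConfig(n_patients=10, grid_shape=(32, 32, 32), seed=11)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def preprocessed_cohort(small_cohort):
    import copy

    cohort = copy.copy(small_cohort)
    cohort.studies = [preprocess_study(s) for s in small_cohort.studies]
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(123)
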