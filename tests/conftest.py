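import numpy as np
import pytest

from memtrace.simcohort import CohortSpec, default_rois, simulate_cohort


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_per_group=2, grid_shape=(12, 12, 12))


@pytest.fixture(scope="session")
def tiny_cohort(small_spec):
    return simulate_cohort(small_spec, seed=7)


@pytest.fixture(scope="session")
def tiny_subject(tiny_cohort):
    return tiny_cohort.subject("sub-000")


@pytest.fixture(scope="session")
def tiny_rois(small_spec):
    return default_rois(small_spec.grid_shape)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
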