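import numpy as np
import pytest

from devcohort.engines.osa import generate_osa_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_table():
    """A small but fully realistic generated dataset for structural tests."""
    return generate_osa_dataset(seed=77, n_subjects=120)
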