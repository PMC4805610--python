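import numpy as np
import pytest

from rehoband.phantom import PhantomConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small two-group cohort reused by read-only tests."""
    return generate_cohort(
        PhantomConfig(n_per_group=(3, 3), grid_shape=(12, 12, 8), rng_seed=11)
    )
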