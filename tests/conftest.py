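import numpy as np
import pytest

from pvscade import phantom


@pytest.fixture(scope="session")
def desk_params():
    """CPU-scale phantom geometry used by most image-level tests."""
    return phantom.desk_params()


@pytest.fixture(scope="session")
def small_cohort(desk_params):
    """Eight seeded subjects (48 parts) at desk geometry."""
    return phantom.generate_cohort(8, desk_params, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
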