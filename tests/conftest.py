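import numpy as np
import pytest

from painequity.cohort import GeneratorParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions (n=16,747, seed 0)."""
    return generate_cohort(GeneratorParams())


@pytest.fixture(scope="session")
def small_cohort():
    """A smaller cohort for fits where full size is unnecessary."""
    return generate_cohort(GeneratorParams(n=4000, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240712)
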