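import numpy as np
import pytest

from mhce import SimConfig, generate_all


@pytest.fixture(scope="session")
def default_bundle():
    """Default study-condition bundle (59 animals), without phasing
    observations; stages that need them generate their own subsets."""
    return generate_all(SimConfig(seed=1), with_phasing=False)


@pytest.fixture(scope="session")
def locus(default_bundle):
    return default_bundle.locus


@pytest.fixture(scope="session")
def cohort(default_bundle):
    return default_bundle.cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(20221219)
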