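import numpy as np
import pytest
from hypothesis import settings

from ace_subtypes import SimConfig, simulate_cohort

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

#: six-group pair counts of the reference design (MZ/DZ x concordant-short,
#: concordant-normal, discordant)
REFERENCE_GROUP_SIZES = {
    "MZ_CS": 151, "MZ_CN": 879, "MZ_D": 337,
    "DZ_CS": 240, "DZ_CN": 1481, "DZ_D": 766,
}


@pytest.fixture(scope="session")
def default_cohort():
    """A 4000-pair cohort under the default generating values."""
    return simulate_cohort(SimConfig(n_pairs=4000, seed=20240917))


@pytest.fixture(scope="session")
def small_cohort():
    """A 900-pair cohort for fast pipeline-level tests."""
    return simulate_cohort(SimConfig(n_pairs=900, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
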