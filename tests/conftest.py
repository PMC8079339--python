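import numpy as np
import pytest

from iplconcord import CohortSpec, build_sector_map, generate_case
from iplconcord.phantom import build_anatomy


@pytest.fixture(scope="session")
def small_spec():
    """A deterministic 3-patient cohort spec on the default grid."""
    return CohortSpec(n_patients=3, seed=11)


@pytest.fixture(scope="session")
def case(small_spec):
    return generate_case(small_spec, 0)


@pytest.fixture(scope="session")
def anatomy():
    return build_anatomy((48, 48, 26), (2.0, 2.0, 3.0), 31.0)


@pytest.fixture(scope="session")
def sector_map(anatomy):
    return build_sector_map(anatomy)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
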