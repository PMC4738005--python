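import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coelute.simulate import SimParams, generate_world

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


#: Small world used by several module tests: fast but structurally complete
#: (two species, conservation loss, dropout, duplicated co-orthologs).
SMALL_PARAMS = SimParams(
    n_species=2,
    n_complexes=10,
    complex_size_range=(3, 5),
    n_monomers=20,
    n_experiments_per_species=2,
    n_fractions=40,
    seed=11,
)


@pytest.fixture(scope="session")
def small_world():
    return generate_world(SMALL_PARAMS)


@pytest.fixture(scope="session")
def default_world():
    """A world at the default study design (2 species, 20 complexes of 3-6
    members, 40 monomers, 2 experiments per species, 60 fractions)."""
    return generate_world(SimParams(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20151212)
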