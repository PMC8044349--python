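import numpy as np
import pytest

from strucnet.cohort import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240321)


@pytest.fixture(scope="session")
def small_null_cohort():
    """Two exchangeable 6-subject groups on a 30-node network (no effects)."""
    spec = CohortSpec(
        n_per_group={"g1": 6, "g2": 6},
        n_nodes=30,
        n_modules=3,
        effect_profiles={},
        seed=7,
    )
    return spec, *generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort at reduced group sizes (AD/SIVD/NC effects)."""
    spec = CohortSpec(n_per_group={"AD": 6, "SIVD": 6, "NC": 6}, seed=11)
    return spec, *generate_cohort(spec)
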