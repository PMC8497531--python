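import numpy as np
import pytest

from fcmega.cohort import CohortConfig, default_atlas, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Modest 4-site cohort with an SMN effect, shared across tests."""
    cfg = CohortConfig(n_sites=4, per_site_n=30, seed=7,
                       group_effect={"SMN": -0.08})
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def atlas42():
    return default_atlas(42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
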