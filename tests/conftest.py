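import numpy as np
import pytest

from eegnorm.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """40 HC + 20 patients over 3 sites — enough for structural tests."""
    cfg = CohortConfig(n_hc_train=30, n_hc_test=10, n_pd=10, n_ad=10,
                       n_sites=3)
    return generate_cohort(cfg, seed=7)
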