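import numpy as np
import pytest

from hemonet.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-patient synthetic cohort shared by read-only tests."""
    cfg = SyntheticConfig(n_patients=20, seed=7)
    cohort, clinical, masks = generate_cohort(cfg)
    return cfg, cohort, clinical, masks


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
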