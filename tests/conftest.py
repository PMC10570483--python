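import numpy as np
import pytest
from hypothesis import settings

from msdyn import SimConfig, make_canonical_templates, simulate_cohort, standard_montage

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def canonical(montage):
    return make_canonical_templates(montage)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort at 20 s / subject, default SNR, fully seeded."""
    cfg = SimConfig(n_high=3, n_low=3, duration_s=20.0, seed=11)
    recs, meta, truth = simulate_cohort(cfg)
    return cfg, recs, meta, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Four subjects rendered without sensor noise (identifiability checks)."""
    cfg = SimConfig(n_high=2, n_low=2, duration_s=20.0, snr=np.inf, seed=12)
    recs, meta, truth = simulate_cohort(cfg)
    return cfg, recs, meta, truth
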