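import numpy as np
import pytest

from tusnet.synthetic import make_connectome_cohort, make_region_table


@pytest.fixture(scope="session")
def small_table():
    return make_region_table(20, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_table):
    # 20-region tables need a higher edge density than the 84-region
    # default to keep the EDR backbone connected.
    return make_connectome_cohort(small_table, n_subjects=5, density=0.6, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, n=4, jitter=0.5):
    """Random symmetric positive-definite matrix with unit-ish diagonal."""
    A = rng.standard_normal((n, n)) * jitter
    S = A @ A.T + n * np.eye(n)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)
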