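import numpy as np
import pytest

from xqtl.grm import compute_grm
from xqtl.synthetic_data import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_cohort():
    """One small single-population cohort shared by read-only tests."""
    cfg = SimConfig(
        seed=1234,
        n_females_per_pop=300,
        n_autosomal_variants=250,
        n_x_variants=150,
        target_h2_aut=0.30,
        target_h2_x=0.05,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def small_grms(small_cohort):
    dm, _, _ = small_cohort
    return (
        compute_grm(dm, chroms=["2"], label="autosomal"),
        compute_grm(dm, chroms=["X"], label="X"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
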