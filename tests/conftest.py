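import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-individual, 2-replicate cohort on a 200-bin chromosome."""
    from hicpop import (SimConfig, default_truth, simulate_cohort_matrices,
                        simulate_genotypes)

    cfg = SimConfig(n_individuals=6, seed=101, chrom_length=8_000_000)
    truth = default_truth(cfg, batch_shift=0.0)
    geno = simulate_genotypes(cfg, 40)
    mats = simulate_cohort_matrices(cfg, truth, geno)
    return cfg, truth, geno, mats


@pytest.fixture(scope="session")
def covariates():
    from hicpop import simulate_bin_covariates

    return simulate_bin_covariates(200, seed=7, zero_fraction=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
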