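import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panels():
    """Compact genotype + protein panels with one planted trans network."""
    from prsprot import simgen

    cfg = simgen.SimConfig(
        n_samples=600, n_snps=12, n_proteins=16, ld_block_size=4,
        ld_rho=0.4, maf_range=(0.15, 0.45),
        network_spec=[([0, 1, 2], [0, 1, 2, 3], 0.25)],
        cis_spec=[(8, 10, 0.4)],
        n_confounders=2, confounder_sd=0.8, noise_sd=1.0, seed=11)
    geno = simgen.simulate_genotypes(cfg)
    proteins, truth, confounders = simgen.simulate_proteins(cfg, geno)
    return cfg, geno, proteins, truth, confounders
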