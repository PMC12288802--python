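import pytest

import humiclink as h


@pytest.fixture(scope="session")
def small_cfg():
    """Two-tissue dataset small enough for fast IO/pipeline exercises."""
    return h.SimulationConfig(
        n_genes=50,
        n_snps=1000,
        n_chromosomes=2,
        chrom_length_bp=1_000_000,
        tissues=("gill", "liver"),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    return h.simulate_dataset(small_cfg)


def power_config(seed: int) -> h.SimulationConfig:
    """Study conditions for the planted-effect power checks: n=32 samples,
    log2FC = 2 for DEGs, beta = 1 at MAF ~0.3 for cis-eQTLs."""
    return h.SimulationConfig(
        n_genes=300,
        n_snps=6_000,
        n_chromosomes=2,
        chrom_length_bp=3_000_000,
        tissues=("gill",),
        deg_fraction_per_tissue=0.2,
        deg_log2fc_range=(2.0, 2.0),
        eqtl_fraction=0.2,
        eqtl_beta_range=(1.0, 1.0),
        eqtl_snp_maf_range=(0.25, 0.35),
        seed=seed,
    )


@pytest.fixture(scope="session")
def power_ds():
    return h.simulate_dataset(power_config(11))
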