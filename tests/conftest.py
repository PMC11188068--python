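import numpy as np
import pytest

from paleoroh import synthetic as sy


@pytest.fixture(scope="session")
def small_panel():
    """40-haplotype panel over two chromosomes, ~1 SNP / 10 kb."""
    cfg = sy.PanelConfig(
        n_haplotypes=40,
        chrom_lengths=[("chr1", 30_000_000), ("chr2", 20_000_000)],
        site_density=1.0 / 10_000,
        seed=11,
    )
    return sy.simulate_panel(cfg)


@pytest.fixture(scope="session")
def recovery_panel():
    """100-Mb genome at 1 SNP / 8 kb, used for F_ROH parameter recovery."""
    cfg = sy.PanelConfig(
        n_haplotypes=40,
        chrom_lengths=[("chr1", 60_000_000), ("chr2", 40_000_000)],
        site_density=1.0 / 8_000,
        seed=11,
    )
    return sy.simulate_panel(cfg)


@pytest.fixture(scope="session")
def truth_genome(small_panel):
    ind = sy.sample_individual(small_panel, "samp", seed=21)
    return sy.plant_roh(ind, target_froh=0.10, seed=22)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
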