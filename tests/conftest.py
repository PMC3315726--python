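import numpy as np
import pandas as pd
import pytest

from taintscan.sim import PlantedQtl, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_sires=20, n_dams=60, offspring_per_dam=2,
        n_snps_per_chrom=40, n_chroms=2, seed=11,
        qtl_spec=(PlantedQtl(chrom=1, snp_start=15, snp_stop=21,
                             causal_haplotype="", beta=0.3),),
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """One simulated cohort reused across read-only tests."""
    ped, geno, pheno, truth = simulate_cohort(small_cfg)
    return dict(cfg=small_cfg, ped=ped, geno=geno, pheno=pheno, truth=truth)


def make_window_genotypes(n_animals, n_snps, seed, adjacent_ld_r=0.8,
                          freq_range=(0.2, 0.8)):
    """Unrelated diploid genotypes over a small window, for phasing tests."""
    from taintscan.sim import SimConfig, simulate_founder_haplotypes

    cfg = SimConfig(n_snps_per_chrom=n_snps, n_chroms=1, seed=seed,
                    adjacent_ld_r=adjacent_ld_r, allele_freq_range=freq_range)
    pool = simulate_founder_haplotypes(cfg, n_haplotypes=2 * n_animals)
    geno = pd.DataFrame(pool[::2] + pool[1::2])
    geno.index = [f"A{i}" for i in range(n_animals)]
    truth = {f"A{i}": (pool[2 * i], pool[2 * i + 1]) for i in range(n_animals)}
    return geno, truth
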