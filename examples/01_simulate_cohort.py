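"""Simulate a half-sib pig cohort and write it in standard formats.

Builds a Duroc-like breed (71 sires x 229 dams, one phenotyped boar per
dam) with LD-structured SNPs and a planted androstenone QTL, then writes
PLINK PED/MAP genotypes, a phenotype CSV and the true phases.
"""

from taintscan.io import write_phenotypes, write_plink, write_truth
from taintscan.sim import PlantedQtl, SimConfig, simulate_cohort, snp_map

cfg = SimConfig(
    n_sires=71, n_dams=229, offspring_per_dam=1,
    n_snps_per_chrom=60, n_chroms=3, adjacent_ld_r=0.9, seed=42,
    qtl_spec=(PlantedQtl(chrom=2, snp_start=22, snp_stop=27,
                         causal_haplotype="", beta=0.3, trait="androstenone"),),
)
ped, geno, pheno, truth = simulate_cohort(cfg)
smap = snp_map(cfg)
geno.columns = smap["snp"]

write_plink(geno, smap, ped, "cohort", breed="SIM")
write_phenotypes(pheno, "cohort_pheno.csv")
write_truth(truth, list(geno.index), "cohort_truth.csv")

off = ped[ped.role == "offspring"]
print(f"{len(off)} phenotyped boars in {off.sire.nunique()} half-sib families")
print(f"{geno.shape[1]} SNPs on {cfg.n_chroms} chromosomes")
print(f"planted QTL: chr{cfg.qtl_spec[0].chrom} "
      f"SNPs {cfg.qtl_spec[0].snp_start}-{cfg.qtl_spec[0].snp_stop}, "
      f"beta={cfg.qtl_spec[0].beta} per h-unit on log10 androstenone")
print("raw androstenone range (ug/g):",
      round(pheno.androstenone.min(), 3), "-", round(pheno.androstenone.max(), 3))
# The log-normal trait and the family sizes mirror the statistical structure
# a boar-taint GWAS assumes; the truth file lets you score phasing later.
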