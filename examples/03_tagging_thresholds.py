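"""Tag-SNP selection and Bonferroni calibration.

Counting every SNP as an independent test over-corrects when SNPs are in
LD; the effective number of tests is the number of tag SNPs (greedy pairwise
tagging at r-squared >= 0.8, per chromosome).
"""

from taintscan.qc import apply_qc_filters
from taintscan.sim import SimConfig, simulate_cohort, snp_map
from taintscan.tagging import bonferroni_thresholds, estimate_r2, select_tags

cfg = SimConfig(n_sires=40, n_dams=120, offspring_per_dam=2,
                n_snps_per_chrom=60, n_chroms=3, adjacent_ld_r=0.9, seed=3)
ped, geno, pheno, _ = simulate_cohort(cfg)
smap = snp_map(cfg)
geno.columns = smap["snp"]
geno_qc, _ = apply_qc_filters(geno.loc[ped.query("role == 'offspring'").animal])

print("EM r2 between two adjacent SNPs:",
      round(estimate_r2(geno_qc.iloc[:, 0], geno_qc.iloc[:, 1]), 3))

tags = select_tags(geno_qc, smap, r2_threshold=0.8)
levels = bonferroni_thresholds(tags, alpha=0.05)
print(f"{geno_qc.shape[1]} QC-passed SNPs -> {tags.n_tags} tag SNPs")
print(f"genome-wide 5% level: p = {levels.genome_wide_p:.3g}")
for chrom, p in levels.per_chromosome_p.items():
    print(f"  chr{chrom}: {tags.tags_per_chrom[chrom]} tags, "
          f"chromosome-wide 5% level p = {p:.3g}")
# Fewer tags than SNPs -> a less punishing multiple-testing correction.
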