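"""Generator checks: pedigree shape, LD structure, Mendelian transmission,
phenotype arithmetic, and the variance/heritability bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from taintscan.sim import (
    PlantedQtl, SimConfig, causal_h, gene_drop, simulate_cohort,
    simulate_founder_haplotypes, simulate_pedigree, simulate_phenotypes,
)


class TestPedigree:
    def test_study_design_counts(self):
        cfg = SimConfig(n_sires=71, n_dams=229, offspring_per_dam=1, seed=0)
        ped = simulate_pedigree(cfg)
        off = ped[ped.role == "offspring"]
        assert len(off) == 229
        assert off.sire.nunique() == 71
        assert (off.groupby("dam").size() == 1).all()

    def test_single_sire_one_half_sib_family(self):
        cfg = SimConfig(n_sires=1, n_dams=30, seed=1)
        off = simulate_pedigree(cfg).query("role == 'offspring'")
        assert off.sire.nunique() == 1

    def test_monogamous_full_sib_pairs(self):
        cfg = SimConfig(n_sires=25, n_dams=25, offspring_per_dam=2, seed=2)
        off = simulate_pedigree(cfg).query("role == 'offspring'")
        fams = off.groupby(["sire", "dam"]).size()
        assert (fams == 2).all()
        assert len(fams) == 25

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_sires=0)
        with pytest.raises(ValueError):
            SimConfig(n_sires=10, n_dams=5)
        with pytest.raises(ValueError):
            SimConfig(offspring_per_dam=3)


class TestFounderHaplotypes:
    def test_independent_sites_have_no_ld(self):
        cfg = SimConfig(n_snps_per_chrom=6, n_chroms=1, adjacent_ld_r=0.0, seed=3)
        pool = simulate_founder_haplotypes(cfg, n_haplotypes=10_000)
        corr = np.corrcoef(pool.T)
        off_diag = corr[np.triu_indices_from(corr, k=1)]
        assert np.max(off_diag ** 2) < 0.002

    def test_high_ld_collapses_haplotype_diversity(self):
        cfg = SimConfig(n_snps_per_chrom=6, n_chroms=1, adjacent_ld_r=0.99,
                        allele_freq_range=(0.5, 0.5), seed=4)
        pool = simulate_founder_haplotypes(cfg, n_haplotypes=500)
        n_distinct = len(np.unique(pool, axis=0))
        assert n_distinct < 2 ** 6

    def test_symmetric_frequencies(self):
        cfg = SimConfig(n_snps_per_chrom=50, n_chroms=1,
                        allele_freq_range=(0.5, 0.5), adjacent_ld_r=0.5, seed=5)
        pool = simulate_founder_haplotypes(cfg, n_haplotypes=4_000)
        assert abs(pool.mean() - 0.5) < 0.02

    def test_adjacent_correlation_matches_target(self):
        cfg = SimConfig(n_snps_per_chrom=20, n_chroms=1, adjacent_ld_r=0.6, seed=6)
        pool = simulate_founder_haplotypes(cfg, n_haplotypes=40_000)
        r = [np.corrcoef(pool[:, j], pool[:, j + 1])[0, 1] for j in range(19)]
        assert np.allclose(r, 0.6, atol=0.02)


class TestGeneDrop:
    def test_no_recombination_copies_a_parental_haplotype(self):
        cfg = SimConfig(n_sires=5, n_dams=10, n_snps_per_chrom=20, n_chroms=1,
                        recomb_rate_per_interval=0.0, seed=7)
        pool = simulate_founder_haplotypes(cfg)
        ped = simulate_pedigree(cfg)
        _, truth = gene_drop(ped, pool, cfg)
        for row in ped.query("role == 'offspring'").itertuples():
            pat, mat = truth.true_phases[row.animal]
            s1, s2 = truth.true_phases[row.sire]
            d1, d2 = truth.true_phases[row.dam]
            assert any(np.array_equal(pat, h) for h in (s1, s2))
            assert any(np.array_equal(mat, h) for h in (d1, d2))

    def test_phase_sums_to_genotype_everywhere(self, small_cohort):
        geno, truth = small_cohort["geno"], small_cohort["truth"]
        for animal in geno.index:
            pat, mat = truth.true_phases[animal]
            assert np.array_equal(pat + mat, geno.loc[animal].to_numpy())

    def test_allele_frequency_conserved_across_generations(self, small_cohort):
        ped, geno = small_cohort["ped"], small_cohort["geno"]
        truth = small_cohort["truth"]
        founders = ped.query("role != 'offspring'").animal
        off = ped.query("role == 'offspring'").animal
        f_founder = geno.loc[founders].mean() / 2
        f_off = geno.loc[off].mean() / 2
        n_chrom = 2 * len(off)
        sd = np.sqrt(f_founder * (1 - f_founder) / n_chrom)
        assert ((f_off - f_founder).abs() <= 3 * sd + 1e-12).mean() > 0.95

    def test_crossover_rate_is_binomial(self):
        cfg = SimConfig(n_sires=2, n_dams=2, n_snps_per_chrom=11, n_chroms=1,
                        recomb_rate_per_interval=0.5, seed=8)
        from taintscan.sim import _gamete
        rng = np.random.default_rng(9)
        a = np.zeros(11, dtype=np.int8)
        b = np.ones(11, dtype=np.int8)
        n_gam = 10_000
        crossings = 0
        for _ in range(n_gam):
            g = _gamete(a, b, cfg, rng)
            crossings += int(np.abs(np.diff(g)).sum())
        total = n_gam * 10
        p_hat = crossings / total
        assert abs(p_hat - 0.5) < 3 * np.sqrt(0.25 / total)


class TestPhenotypes:
    def _mini(self, **kw):
        base = dict(n_sires=5, n_dams=10, n_snps_per_chrom=10, n_chroms=1, seed=10)
        base.update(kw)
        return SimConfig(**base)

    def test_degenerate_no_noise_no_effect(self):
        vc = dict.fromkeys(["sire", "dam", "season", "pen", "herd", "residual"], 0.0)
        cfg = self._mini(variance_components=vc, trait_mean_log10=0.3)
        _, _, pheno, _ = simulate_cohort(cfg)
        assert np.allclose(pheno["androstenone"], 10 ** 0.3)

    def test_h_coding_effect_arithmetic(self):
        vc = dict.fromkeys(["sire", "dam", "season", "pen", "herd", "residual"], 0.0)
        cfg = self._mini(
            variance_components=vc,
            qtl_spec=(PlantedQtl(1, 0, 3, "", 0.3, "androstenone"),),
            n_dams=40, n_sires=10,
        )
        ped, geno, pheno, truth = simulate_cohort(cfg)
        qtl = truth.qtl_spec[0]
        h = causal_h(truth, qtl, pheno["animal"], cfg)
        logy = np.log10(pheno["androstenone"])
        if (h == 1).any() and (h == -1).any():
            assert np.isclose(logy[h == 1].mean() - logy[h == -1].mean(), 0.6)
        assert np.allclose(logy - 0.3 * h, cfg.trait_mean_log10)

    def test_total_variance_decomposes(self):
        cfg = self._mini(n_sires=20, n_dams=60, offspring_per_dam=2, seed=12)
        ped, geno, pheno, truth = simulate_cohort(cfg)
        total = sum(cfg.variance_components.values())
        # 200 fresh phenotype draws on the fixed pedigree/genotypes
        var_hat = []
        for rep in range(200):
            p = simulate_phenotypes(ped, truth, cfg,
                                    rng=np.random.default_rng(1000 + rep))
            var_hat.append(np.log10(p["skatole"]).var(ddof=1))
        assert abs(np.mean(var_hat) - total) / total < 0.10

    def test_half_sib_intraclass_correlation(self):
        vc = dict.fromkeys(["dam", "season", "pen", "herd"], 0.0)
        vc.update(sire=0.03, residual=0.07)
        cfg = SimConfig(n_sires=60, n_dams=600, offspring_per_dam=1,
                        n_snps_per_chrom=5, n_chroms=1,
                        variance_components=vc, seed=13)
        ped, _, _, truth = simulate_cohort(cfg)
        reps = []
        for rep in range(20):
            pheno = simulate_phenotypes(ped, truth, cfg,
                                        rng=np.random.default_rng(2000 + rep))
            df = pheno.assign(y=np.log10(pheno["indole"]))
            grand = df.y.mean()
            groups = df.groupby("sire").y
            k = groups.size().mean()
            msb = (groups.size() * (groups.mean() - grand) ** 2).sum() / (groups.ngroups - 1)
            msw = groups.apply(lambda g: ((g - g.mean()) ** 2).sum()).sum() / (len(df) - groups.ngroups)
            s2_b = (msb - msw) / k
            reps.append(s2_b / (s2_b + msw))
        expected = 0.03 / 0.10
        assert abs(np.mean(reps) - expected) < 0.05
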