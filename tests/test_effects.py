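"""Haplotype-effect mixed model: h-coding, focal selection, fits, adjustments."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from taintscan.effects import (
    EffectEstimate, allele_h, anova_screen, body_trait_adjustment,
    code_haplotype_copies, fit_haplotype_model, make_model_frame,
    select_focal_haplotype, single_snp_effect, variance_explained,
)
from taintscan.treephase import HaplotypeCatalog, PhaseAssignment


def simulate_effect_data(beta, n=200, seed=0, vc=None, n_sires=20):
    """Direct draw from the analysis model (bypasses genotypes)."""
    rng = np.random.default_rng(seed)
    vc = vc or dict(sire=0.012, dam=0.012, season=0.004, pen=0.004,
                    herd=0.004, residual=0.055)
    sire = rng.integers(0, n_sires, n)
    dam = rng.integers(0, n // 2, n)
    season = rng.integers(0, 6, n)
    pen = rng.integers(0, 10, n)
    herd = rng.integers(0, 15, n)
    h = rng.choice([-1, 0, 1], n, p=[0.3, 0.5, 0.2])
    y = (0.45 + beta * h
         + np.sqrt(vc["sire"]) * rng.standard_normal(n_sires)[sire]
         + np.sqrt(vc["dam"]) * rng.standard_normal(n // 2)[dam]
         + np.sqrt(vc["season"]) * rng.standard_normal(6)[season]
         + np.sqrt(vc["pen"]) * rng.standard_normal(10)[pen]
         + np.sqrt(vc["herd"]) * rng.standard_normal(15)[herd]
         + np.sqrt(vc["residual"]) * rng.standard_normal(n))
    return pd.DataFrame({
        "y": y, "h": h,
        "sire": sire.astype(str), "dam": dam.astype(str),
        "season": season.astype(str), "pen": pen.astype(str),
        "herd": herd.astype(str),
    })


class TestHCoding:
    @pytest.mark.parametrize("copies,h", [(2, 1), (1, 0), (0, -1)])
    def test_mapping(self, copies, h):
        assert code_haplotype_copies(copies) == h

    @given(st.integers(min_value=-3, max_value=5))
    def test_bijection_and_domain(self, copies):
        if copies in (0, 1, 2):
            assert code_haplotype_copies(copies) == copies - 1
        else:
            with pytest.raises(ValueError):
                code_haplotype_copies(copies)


def _catalog(freqs):
    true = sorted((h for h, f in freqs.items() if f > 0.015),
                  key=lambda h: -freqs[h])
    return HaplotypeCatalog(frequencies=freqs, counts={},
                            true_haplotypes=true, coverage_percent=90.0,
                            n_chromosomes=200)


def _assignments(hap_pairs):
    return [PhaseAssignment(f"A{i}", h1, h2, "tree-phased")
            for i, (h1, h2) in enumerate(hap_pairs)]


class TestSelectFocal:
    def test_most_frequent_by_default(self):
        pairs = [("11", "11")] * 30 + [("00", "11")] * 10 + [("00", "01")] * 10
        assigns = _assignments(pairs)
        trait = pd.Series(1.0, index=[a.animal for a in assigns])
        cat = _catalog({"11": 0.6, "00": 0.3, "01": 0.1})
        hap, freq = select_focal_haplotype(cat, assigns, trait)
        assert hap == "11" and freq == 0.6

    def test_second_substituted_when_similar_counts_and_larger_deviation(self):
        pairs = [("11", "11")] * 15 + [("11", "00")] * 12 + [("00", "01")] * 10
        assigns = _assignments(pairs)
        vals = {a.animal: (2.0 if "00" in (a.hap1, a.hap2) else 0.0)
                for a in assigns}
        trait = pd.Series(vals)
        cat = _catalog({"11": 42 / 74, "00": 22 / 74, "01": 10 / 74})
        hap, _ = select_focal_haplotype(cat, assigns, trait)
        assert hap == "00"

    def test_second_rejected_when_counts_dissimilar(self):
        pairs = [("11", "11")] * 40 + [("00", "11")] * 5 + [("01", "11")] * 5
        assigns = _assignments(pairs)
        vals = {a.animal: (3.0 if "00" in (a.hap1, a.hap2) else 0.0)
                for a in assigns}
        cat = _catalog({"11": 0.8, "00": 0.1, "01": 0.1})
        hap, _ = select_focal_haplotype(cat, assigns, pd.Series(vals))
        assert hap == "11"

    def test_no_true_haplotypes_raises(self):
        cat = _catalog({"11": 0.01, "00": 0.01})
        with pytest.raises(LookupError):
            select_focal_haplotype(cat, [], pd.Series(dtype=float))


class TestAnovaScreen:
    def test_two_classes_equals_t_test(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(60)
        h = np.repeat([0, 1], 30)
        p_anova = anova_screen(y, h)
        p_t = stats.ttest_ind(y[h == 0], y[h == 1]).pvalue
        assert p_anova == pytest.approx(p_t, rel=1e-10)

    def test_separated_means_tiny_p(self):
        y = np.concatenate([np.full(20, 1.0), np.full(20, 2.0), np.full(20, 3.0)])
        y += np.random.default_rng(2).normal(0, 1e-4, 60)
        assert anova_screen(y, np.repeat([-1, 0, 1], 20)) < 1e-10

    def test_single_class_p_one(self):
        assert anova_screen(np.arange(5.0), np.zeros(5)) == 1.0


class TestFitHaplotypeModel:
    def test_degenerate_limit_equals_ols(self):
        # structurally absent random effects (single level each): the fit
        # must collapse to ordinary least squares exactly
        vc0 = dict(sire=0, dam=0, season=0, pen=0, herd=0, residual=0.05)
        data = simulate_effect_data(0.3, n=250, seed=3, vc=vc0)
        for f in ("sire", "dam", "season", "pen", "herd"):
            data[f] = "0"
        est = fit_haplotype_model(data, test="wald")
        ols = stats.linregress(data["h"], data["y"])
        assert est.beta_hat == pytest.approx(ols.slope, abs=1e-6)

    def test_recovers_planted_effect(self):
        betas = [fit_haplotype_model(simulate_effect_data(0.3, n=250, seed=s),
                                     test="wald").beta_hat
                 for s in range(12)]
        assert abs(np.mean(betas) - 0.3) < 0.02

    def test_lrt_null_p_roughly_uniform(self):
        ps = [fit_haplotype_model(simulate_effect_data(0.0, n=120, seed=s,
                                                       n_sires=12)).p_value
              for s in range(40)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_h_class_rejected(self):
        data = simulate_effect_data(0.0, n=60, seed=5)
        data["h"] = 0
        with pytest.raises(ValueError):
            fit_haplotype_model(data)

    def test_raw_scale_effect_is_homozygote_contrast(self):
        data = simulate_effect_data(0.25, n=250, seed=6)
        est = fit_haplotype_model(data, test="wald")
        expected = 10 ** (est.mu_hat + est.beta_hat) - 10 ** (est.mu_hat - est.beta_hat)
        assert est.raw_scale_effect == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [0, 2, 5])
    def test_matches_statsmodels_mixedlm(self, seed):
        # independent route: statsmodels MixedLM with the crossed factors as
        # variance components (l-bfgs fit refined by warm-started Powell)
        import warnings
        import statsmodels.formula.api as smf

        data = simulate_effect_data(0.3, n=250, seed=seed, n_sires=30)
        est = fit_haplotype_model(data, test="wald")
        vc = {f: f"0 + C({f})" for f in ("sire", "dam", "season", "pen", "herd")}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("y ~ h", data, groups=np.ones(len(data)),
                                vc_formula=vc)
            first = model.fit(reml=True, method="lbfgs", maxiter=200)
            ref = model.fit(reml=True, method="powell", maxiter=200,
                            start_params=first.params_object)
            if ref.llf < first.llf:
                ref = first
        assert est.beta_hat == pytest.approx(float(ref.fe_params["h"]), abs=1e-3)
        assert est.beta_se == pytest.approx(float(ref.bse_fe["h"]), rel=0.05)

    def test_matches_lme4_reference_fit(self, tmp_path):
        data = simulate_effect_data(0.3, n=200, seed=7)
        est = fit_haplotype_model(data, test="wald")
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}", colClasses=c(sire="factor", dam="factor",
                          season="factor", pen="factor", herd="factor"))
            m <- lmer(y ~ h + (1|sire) + (1|dam) + (1|season) + (1|pen) + (1|herd),
                      data=d, REML=TRUE)
            cat(fixef(m)["h"], "\\n")
        """)
        rs = tmp_path / "fit.R"
        rs.write_text(script)
        try:
            out = subprocess.run(["Rscript", str(rs)], capture_output=True,
                                 text=True, timeout=120, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.skip(f"lme4 reference unavailable: {exc}")
        beta_lme4 = float(out.stdout.strip().split()[-1])
        assert est.beta_hat == pytest.approx(beta_lme4, abs=2e-3)


class TestVarianceExplained:
    def test_zero_beta(self):
        assert variance_explained(0.0, [1, 0, -1], [1.0, 2.0, 3.0]) == 0.0

    def test_zero_h_variance(self):
        assert variance_explained(0.5, [0, 0, 0], [1.0, 2.0, 3.0]) == 0.0

    def test_single_cause_simulation_near_truth(self):
        # beta^2 Var(h) tuned to ~15% of total variance
        vals = []
        for s in range(25):
            data = simulate_effect_data(0.15, n=300, seed=100 + s)
            est = fit_haplotype_model(data, test="wald")
            vals.append(est.variance_explained)
        data_all = simulate_effect_data(0.15, n=4000, seed=999)
        target = 0.15 ** 2 * data_all["h"].var() / data_all["y"].var()
        assert abs(np.mean(vals) - target) < 0.03


class TestBodyTraits:
    def _pheno_with_h(self, seed, weight_from_h=0.0, n=200):
        rng = np.random.default_rng(seed)
        data = simulate_effect_data(0.0, n=n, seed=seed)
        pheno = data.rename(columns={"y": "androstenone"}).copy()
        pheno["androstenone"] = 10 ** pheno["androstenone"]
        pheno["animal"] = [f"A{i}" for i in range(n)]
        pheno["slaughter_weight"] = 100 + weight_from_h * data["h"] \
            + 4 * rng.standard_normal(n)
        pheno["meat_content"] = 60 + 2 * rng.standard_normal(n)
        h = pd.Series(data["h"].to_numpy(), index=pheno["animal"])
        return pheno, h

    def test_null_body_traits_rarely_trigger_refit(self):
        triggered = 0
        for s in range(20):
            pheno, h = self._pheno_with_h(s, n=150)
            _, adjusted = body_trait_adjustment(pheno, h, "androstenone",
                                                test="wald")
            triggered += adjusted is not None
        assert triggered <= 4  # ~two alpha=0.05 screens per replicate

    def test_mediated_effect_attenuates_after_adjustment(self):
        # haplotype influences the trait only through slaughter weight
        attenuated = 0
        reps = 12
        for s in range(reps):
            rng = np.random.default_rng(77_000 + s)  # independent of weight noise
            n = 200
            pheno, h = self._pheno_with_h(500 + s, weight_from_h=3.0, n=n)
            w = pheno["slaughter_weight"].to_numpy()
            pheno["androstenone"] = 10 ** (
                0.45 + 0.02 * (w - 100) + 0.15 * rng.standard_normal(n))
            data = make_model_frame(pheno, h, "androstenone")
            unadj = fit_haplotype_model(data, test="wald")
            _, adj = body_trait_adjustment(pheno, h, "androstenone", test="wald")
            if adj is not None and abs(adj.beta_hat) < abs(unadj.beta_hat):
                attenuated += 1
        assert attenuated >= reps * 0.6


class TestSingleSnp:
    def test_monomorphic_snp_rejected(self):
        dos = pd.Series(np.zeros(50, dtype=int),
                        index=[f"A{i}" for i in range(50)])
        with pytest.raises(ValueError):
            allele_h(dos)

    def test_allele_h_uses_major_allele(self):
        dos = pd.Series([2, 2, 2, 1, 1, 0], index=list("abcdef"))
        h = allele_h(dos)
        assert list(h) == [1, 1, 1, 0, 0, -1]
        flipped = allele_h(2 - dos)
        assert list(flipped) == [1, 1, 1, 0, 0, -1]

    def test_recovers_effect_through_perfect_ld_snp(self):
        data = simulate_effect_data(0.3, n=250, seed=11)
        pheno = data.rename(columns={"y": "androstenone"}).copy()
        pheno["androstenone"] = 10 ** pheno["androstenone"]
        pheno["animal"] = [f"A{i}" for i in range(len(data))]
        dos = pd.Series(data["h"].to_numpy() + 1, index=pheno["animal"])
        est = single_snp_effect(dos, pheno, "androstenone", test="wald")
        # major-allele coding may flip the contrast's sign; the magnitude
        # must recover the planted effect
        assert abs(est.beta_hat) == pytest.approx(0.3, abs=3 * est.beta_se)
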