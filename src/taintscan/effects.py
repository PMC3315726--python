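"""Additive fixed-effect tests for the focal haplotype of a QTL region.

The trait model on the log10 scale is

    Y_i = mu + beta * h_i + b_sire(i) + d_dam(i) + s_season(i)
              + p_pen(i) + k_herd(i) + e_i

with independent Gaussian random effects for sire (half-sib family), dam
(nuclear family), season, pen and herd, and h_i coding copies of the focal
haplotype: 1 for two copies, 0 for one, -1 for none.  beta is the additive
effect per h-unit; its test against beta = 0 is a 1-df likelihood-ratio test
on maximum-likelihood fits (a Wald test is available).  The crossed
variance-components model is fitted by REML (see ``taintscan.vcreml``).

The raw-scale effect reported for log10 traits is the contrast between the
two homozygote classes' back-transformed expectations,
10**(mu+beta) - 10**(mu-beta); for traits modelled on their natural scale
(slaughter weight, meat content) it is the homozygote difference 2*beta.
Variance explained is beta^2 Var(h) / Var(Y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

RANDOM_FACTORS = ("sire", "dam", "season", "pen", "herd")


def code_haplotype_copies(copies: int) -> int:
    """h-coding of focal-haplotype copies: 2 -> 1, 1 -> 0, 0 -> -1."""
    if copies not in (0, 1, 2):
        raise ValueError(f"copies must be in {{0,1,2}}, got {copies!r}")
    return copies - 1


def haplotype_h(assignments, focal: str) -> pd.Series:
    """Per-animal h value for a focal haplotype from phase assignments."""
    vals = {}
    for a in assignments:
        copies = int(a.hap1 == focal) + int(a.hap2 == focal)
        vals[a.animal] = code_haplotype_copies(copies)
    return pd.Series(vals, name="h")


def allele_h(dosages: pd.Series) -> pd.Series:
    """h value from copies of the most frequent allele of a single SNP."""
    d = dosages[dosages >= 0]
    p1 = d.sum() / (2 * len(d))
    if p1 in (0.0, 1.0):
        raise ValueError("SNP is monomorphic; no allele contrast to test")
    copies = dosages if p1 >= 0.5 else 2 - dosages
    return (copies - 1).rename("h")


def select_focal_haplotype(catalog, assignments, trait_values: pd.Series,
                           count_tolerance: float = 0.25):
    """Choose the haplotype to test: usually the most frequent true one.

    The second most frequent true haplotype is substituted only when its
    carrier mean deviates more from the overall mean AND the two carrier
    counts differ by at most ``count_tolerance`` (relative to the larger).
    Returns (haplotype, frequency).  Raises LookupError when the catalog has
    no true haplotypes.
    """
    true_haps = catalog.true_haplotypes
    if not true_haps:
        raise LookupError("no haplotype above the 1.5% frequency cutoff")
    first = true_haps[0]
    if len(true_haps) == 1:
        return first, catalog.frequencies[first]
    second = true_haps[1]
    overall = trait_values.mean()

    def carrier_stats(hap):
        carriers = [a.animal for a in assignments if hap in (a.hap1, a.hap2)]
        vals = trait_values.reindex(carriers).dropna()
        return len(vals), abs(vals.mean() - overall) if len(vals) else 0.0

    n1, dev1 = carrier_stats(first)
    n2, dev2 = carrier_stats(second)
    similar = max(n1, n2) > 0 and abs(n1 - n2) / max(n1, n2) <= count_tolerance
    if dev2 > dev1 and similar:
        return second, catalog.frequencies[second]
    return first, catalog.frequencies[first]


def anova_screen(trait, h) -> float:
    """One-way ANOVA of the trait across h classes (pre-screen)."""
    trait = np.asarray(trait, dtype=float)
    h = np.asarray(h)
    groups = [trait[h == v] for v in np.unique(h)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return 1.0
    _, p = stats.f_oneway(*groups)
    return float(p) if np.isfinite(p) else 1.0


@dataclass
class EffectEstimate:
    beta_hat: float
    beta_se: float
    mu_hat: float
    p_value: float
    raw_scale_effect: float
    variance_explained: float
    focal_haplotype: str | None = None
    focal_frequency: float | None = None
    covariates: tuple = ()
    converged: bool = True
    variance_components: dict = field(default_factory=dict)
    method: str = "lmm-lrt"


def _design(data: pd.DataFrame, fixed_terms):
    """X matrix (intercept first) and level codes for active random factors."""
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    for term in fixed_terms:
        cols.append(data[term].to_numpy(dtype=float))
        names.append(term)
    X = np.column_stack(cols)
    codes = {
        f: pd.Categorical(data[f]).codes.astype(int)
        for f in RANDOM_FACTORS
        if data[f].nunique() > 1
    }
    return X, names, codes


def _fit_vc(data: pd.DataFrame, fixed_terms, reml: bool):
    from .vcreml import fit_variance_components

    X, names, codes = _design(data, fixed_terms)
    fit = fit_variance_components(data["y"].to_numpy(), X, codes, reml=reml)
    fit.fe_names = names
    return fit


def _lrt_pvalue(data: pd.DataFrame, fixed) -> float:
    """1-df LRT for the h term on maximum-likelihood fits."""
    full = _fit_vc(data, fixed, reml=False)
    null = _fit_vc(data, [c for c in fixed if c != "h"], reml=False)
    lrt = max(0.0, 2 * (full.llf - null.llf))
    return float(stats.chi2.sf(lrt, df=1))


def make_model_frame(pheno: pd.DataFrame, h: pd.Series, trait: str,
                     log10_scale: bool = True) -> pd.DataFrame:
    """Assemble the modelling frame: response, h, grouping factors, covariates."""
    from .assoc import log10_trait

    df = pheno.set_index("animal").loc[h.index].copy()
    df["y"] = log10_trait(df[trait]) if log10_scale else df[trait].astype(float)
    df["h"] = h
    for f in RANDOM_FACTORS:
        df[f] = df[f].astype(str)
    return df.reset_index()


def fit_haplotype_model(data: pd.DataFrame, covariates=(), test: str = "lrt",
                        response_scale: str = "log10") -> EffectEstimate:
    """REML fit of the additive haplotype model; test of beta = 0.

    ``data`` must carry columns y, h, sire, dam, season, pen, herd (plus any
    covariates).  The LRT compares ML fits with and without the h term; on
    non-convergence the estimate falls back to the one-way ANOVA screen.
    """
    if data["h"].nunique() < 2:
        raise ValueError("need at least two h classes to test the haplotype")
    fixed = ["h"] + list(covariates)
    try:
        fit = _fit_vc(data, fixed, reml=True)
        beta = float(fit.beta[fit.fe_names.index("h")])
        se = float(fit.beta_se[fit.fe_names.index("h")])
        mu = float(fit.beta[0])
        if test == "wald":
            p = float(2 * stats.norm.sf(abs(beta / se)))
        else:
            p = _lrt_pvalue(data, fixed)
        vcomp = dict(fit.variances)
        converged = fit.converged
    except (np.linalg.LinAlgError, ValueError):
        beta = np.nan
        se = np.nan
        mu = float(data["y"].mean())
        p = anova_screen(data["y"], data["h"])
        return EffectEstimate(beta, se, mu, p, np.nan, np.nan,
                              covariates=tuple(covariates), converged=False,
                              method="anova-fallback")
    if response_scale == "log10":
        raw_effect = 10.0 ** (mu + beta) - 10.0 ** (mu - beta)
    else:
        raw_effect = 2 * beta
    ve = variance_explained(beta, data["h"], data["y"])
    return EffectEstimate(
        beta_hat=beta, beta_se=se, mu_hat=mu, p_value=p,
        raw_scale_effect=float(raw_effect), variance_explained=ve,
        covariates=tuple(covariates), converged=converged,
        variance_components=vcomp,
        method=f"lmm-{test}",
    )


def variance_explained(beta: float, h, y) -> float:
    """Share of phenotypic variance attributed to the haplotype: b^2 Var(h)/Var(Y)."""
    h = np.asarray(h, dtype=float)
    y = np.asarray(y, dtype=float)
    var_y = y.var()
    if var_y == 0 or not np.isfinite(beta):
        return np.nan if var_y == 0 else 0.0
    return float(np.clip(beta ** 2 * h.var() / var_y, 0.0, 1.0))


def body_trait_adjustment(pheno: pd.DataFrame, h: pd.Series, trait: str,
                          alpha: float = 0.05, test: str = "wald"):
    """Body-trait screen and covariate-adjusted refit of the taint model.

    Fits the same mixed model with slaughter weight, then meat content, as
    the response; body traits differentiated by the haplotype at ``alpha``
    are added as fixed covariates to a refit of the taint model.  The screen
    defaults to the cheaper Wald test; the refit inherits ``test``.  Returns
    ``(body_results, adjusted_estimate_or_None)``.
    """
    body_results = {}
    significant = []
    for body in ("slaughter_weight", "meat_content"):
        if body not in pheno.columns or pheno[body].isna().all():
            continue
        bdata = make_model_frame(pheno, h, body, log10_scale=False)
        est = fit_haplotype_model(bdata, test=test, response_scale="natural")
        body_results[body] = est
        if est.p_value < alpha:
            significant.append(body)
    adjusted = None
    if significant:
        tdata = make_model_frame(pheno, h, trait, log10_scale=True)
        for body in significant:
            tdata[body] = pheno.set_index("animal").loc[h.index, body].to_numpy()
        adjusted = fit_haplotype_model(tdata, covariates=tuple(significant), test=test)
    return body_results, adjusted


def single_snp_effect(dosages: pd.Series, pheno: pd.DataFrame, trait: str,
                      test: str = "lrt") -> EffectEstimate:
    """Single-SNP QTL: the same mixed model on carrier status of the major allele."""
    h = allele_h(dosages)
    data = make_model_frame(pheno, h, trait, log10_scale=True)
    est = fit_haplotype_model(data, test=test)
    est.focal_haplotype = "major-allele"
    return est
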