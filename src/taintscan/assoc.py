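"""The two genome-wide scans: naive total association and family-aware max(T).

Scan one: simple regression of the (log10, season/pen-adjusted) trait on
allele dosage with an F-test — deliberately ignoring family structure, so it
serves as a liberal first pass.  Scan two: the same regression statistic
referred to a permutation null that preserves the half-sib family structure
(trait values are shuffled only among offspring of the same sire), with
family-wise max(T) multiplicity control across the scanned SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sim import MISSING
from .tagging import SignificanceLevels

ADJUST_FACTORS = ("season", "pen")


def log10_trait(values, zero_shift: bool = True) -> np.ndarray:
    """log10 transform of raw trait values; zeros get half the smallest positive.

    The raw taint measurements can include exact zeros (censored at the assay
    floor); log10(0) is undefined, so zeros are shifted to half the smallest
    positive observed value before transforming.
    """
    v = np.asarray(values, dtype=float).copy()
    if zero_shift and (v == 0).any():
        pos = v[v > 0]
        if pos.size == 0:
            raise ValueError("trait has no positive values")
        v[v == 0] = pos.min() / 2
    if (v <= 0).any():
        raise ValueError("trait has negative values; cannot log-transform")
    return np.log10(v)


def adjust_phenotype(pheno: pd.DataFrame, trait: str, factors=ADJUST_FACTORS,
                     screen_alpha: float = 0.05) -> np.ndarray:
    """Season/pen adjustment of an already log10-transformed trait.

    Each factor is screened by one-way ANOVA; factors influential at
    ``screen_alpha`` are regressed out jointly, and the residuals plus the
    grand mean are returned.  Factors with a single level are skipped.
    """
    y = np.asarray(pheno[trait], dtype=float)
    if np.ptp(y) == 0:
        return y.copy()
    active = []
    for f in factors:
        levels = pd.Categorical(pheno[f])
        if len(levels.categories) < 2:
            continue
        groups = [y[levels.codes == k] for k in range(len(levels.categories))]
        groups = [g for g in groups if len(g) > 0]
        _, p = stats.f_oneway(*groups)
        if np.isfinite(p) and p < screen_alpha:
            active.append(f)
    if not active:
        return y.copy()
    X = [np.ones(len(y))]
    for f in active:
        codes = pd.Categorical(pheno[f]).codes
        dummies = np.eye(codes.max() + 1)[codes][:, 1:]  # drop reference level
        X.append(dummies)
    X = np.column_stack(X)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid + y.mean()


def total_f_test(adjusted_trait, dosages):
    """Naive single-SNP association: F-test of the regression on dosage.

    Returns ``(F, p)`` with (1, n-2) degrees of freedom; family structure is
    intentionally not accounted for.  A SNP with zero dosage variance in the
    analysis set yields ``(nan, nan)``.
    """
    y = np.asarray(adjusted_trait, dtype=float)
    x = np.asarray(dosages, dtype=float)
    ok = (x != MISSING) & np.isfinite(y)
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 jointly observed samples")
    if np.ptp(x) == 0:
        return np.nan, np.nan
    xc = x - x.mean()
    yc = y - y.mean()
    ssx = xc @ xc
    b = (xc @ yc) / ssx
    ss_reg = b * b * ssx
    ss_res = yc @ yc - ss_reg
    if ss_res <= 0:
        return np.inf, 0.0
    f = ss_reg / (ss_res / (n - 2))
    return float(f), float(stats.f.sf(f, 1, n - 2))


def _t_stats(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """|t| of the dosage regression for each SNP column; rows of y are permutations."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    Y = np.atleast_2d(y)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sy = np.sqrt((Yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ Xc) / np.outer(sy, sx)
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = np.abs(r) * np.sqrt((n - 2) / (1 - r ** 2))
    t[:, sx == 0] = 0.0
    t[sy == 0, :] = 0.0
    return t if y.ndim > 1 else t[0]


def _impute_mean(genotypes: pd.DataFrame) -> np.ndarray:
    X = genotypes.to_numpy(dtype=float)
    miss = X == MISSING
    if miss.any():
        X = np.where(miss, np.nan, X)
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    return X


def qfam_total_scan(adjusted_trait, genotypes: pd.DataFrame, pedigree: pd.DataFrame,
                    n_perm: int = 10_000, seed: int = 0) -> pd.Series:
    """Family-aware scan: within-half-sib-family permutations with max(T).

    The observed statistic per SNP is |t| from the regression of the adjusted
    trait on dosage.  The permutation null shuffles trait values only among
    offspring sharing a sire, leaving between-family contrasts intact; the
    family-wise empirical p-value of SNP j is

        (1 + #{permutations whose maximum |t| over SNPs >= |t_j|}) / (n_perm + 1).

    Missing dosages are mean-imputed for this scan.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(adjusted_trait, dtype=float)
    X = _impute_mean(genotypes)
    n = len(y)
    ped = pedigree.set_index("animal")
    fam = pd.Categorical(ped.loc[genotypes.index, "sire"]).codes
    rng = np.random.default_rng(seed)
    t_obs = _t_stats(y, X)

    perm_idx = np.tile(np.arange(n), (n_perm, 1))
    for code in np.unique(fam):
        block = np.flatnonzero(fam == code)
        if len(block) < 2:
            continue
        keys = rng.random((n_perm, len(block)))
        perm_idx[:, block] = block[np.argsort(keys, axis=1)]
    t_perm = _t_stats(y[perm_idx], X)
    max_t = t_perm.max(axis=1)
    # ties count as exceedances (conservative); the epsilon absorbs float
    # noise from re-summing permuted values
    exceed = (max_t[:, None] + 1e-9 >= t_obs[None, :]).sum(axis=0)
    emp_p = (1 + exceed) / (n_perm + 1)
    return pd.Series(emp_p, index=genotypes.columns, name="emp_p")


@dataclass
class AssocResult:
    """Per-SNP statistics of both scans for one breed x trait."""

    table: pd.DataFrame   # snp, chrom, bp, f_statistic, p_naive, emp_p, n_used, suggestive
    trait: str
    breed: str
    thresholds: SignificanceLevels


def genome_scan(pheno: pd.DataFrame, genotypes: pd.DataFrame, pedigree: pd.DataFrame,
                snpmap: pd.DataFrame, thresholds: SignificanceLevels, trait: str,
                breed: str = "SIM", n_perm: int = 10_000, seed: int = 0,
                already_log10: bool = False) -> AssocResult:
    """Run both scans for one trait and flag suggestive SNPs.

    A SNP is suggestive when either test beats the 5% Bonferroni
    chromosome-wide threshold of its chromosome.
    """
    pheno = pheno.set_index("animal").loc[genotypes.index].reset_index()
    work = pheno.copy()
    work[trait] = work[trait] if already_log10 else log10_trait(work[trait])
    y_adj = adjust_phenotype(work, trait)
    smap = snpmap.set_index("snp") if "snp" in snpmap.columns else snpmap
    smap = smap.loc[genotypes.columns]

    fp = np.array([total_f_test(y_adj, genotypes[c]) for c in genotypes.columns])
    emp_p = qfam_total_scan(y_adj, genotypes, pedigree, n_perm=n_perm, seed=seed)
    n_used = (genotypes != MISSING).sum(axis=0).to_numpy()

    chrom_thr = smap["chrom"].map(thresholds.per_chromosome_p).to_numpy()
    p_naive = fp[:, 1]
    suggestive = (
        (np.nan_to_num(p_naive, nan=1.0) < chrom_thr)
        | (emp_p.to_numpy() < chrom_thr)
    )
    table = pd.DataFrame({
        "snp": genotypes.columns,
        "chrom": smap["chrom"].to_numpy(),
        "bp": smap["bp"].to_numpy(),
        "f_statistic": fp[:, 0],
        "p_naive": p_naive,
        "emp_p": emp_p.to_numpy(),
        "n_used": n_used,
        "suggestive": suggestive,
    })
    return AssocResult(table=table, trait=trait, breed=breed, thresholds=thresholds)
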