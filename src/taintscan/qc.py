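"""Per-breed genotype validation: call rates, Hardy-Weinberg proportions, MAF.

Filters are applied to one breed at a time (the downstream association scans
do not model population stratification, so breeds are never pooled).  The
filter order is: sample call rate, SNP call frequency, Hardy-Weinberg exact
test, minor allele frequency; removal counts are reported per filter and are
order-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .sim import MISSING


@dataclass
class QCReport:
    n_samples_removed: int
    n_snps_removed_callrate: int
    n_snps_removed_hwp: int
    n_snps_removed_maf: int
    n_snps_segregating: int
    maf: pd.Series
    hwp_p: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "filter": ["sample_callrate", "snp_callrate", "hwp", "maf"],
            "removed": [self.n_samples_removed, self.n_snps_removed_callrate,
                        self.n_snps_removed_hwp, self.n_snps_removed_maf],
        })


def compute_maf(dosages) -> float:
    """Minor allele frequency of a dosage vector (0/1/2, MISSING allowed)."""
    d = np.asarray(dosages)
    ok = d != MISSING
    n = int(ok.sum())
    if n == 0:
        return np.nan
    p = d[ok].sum() / (2 * n)
    return float(min(p, 1 - p))


def _hwe_pvalues_all(n_minor: int, n_total: int) -> np.ndarray:
    """Exact HWE p-value for every compatible heterozygote count.

    Given ``n_minor`` copies of the rarer allele among ``2*n_total`` alleles,
    the conditional distribution of the heterozygote count n_het given the
    allele counts is

        P(n_het) = C(n, nAA) C(n - nAA, nAb... )  -- standard exact HWE law,

    computed here through log-factorials.  Compatible heterozygote counts
    share the parity of n_minor and run from n_minor % 2 up to min(n_minor,
    2*n_total - n_minor).  Returns the two-sided exact p-value (sum of
    probabilities <= the observed configuration's) indexed by
    ``(n_het - n_minor % 2) // 2``.
    """
    n_major = 2 * n_total - n_minor
    hets = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = (n_major - hets) // 2
    logp = (
        hets * np.log(2.0)
        + gammaln(n_total + 1)
        - gammaln(hom_minor + 1) - gammaln(hets + 1) - gammaln(hom_major + 1)
        + gammaln(n_minor + 1) + gammaln(n_major + 1) - gammaln(2 * n_total + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    # include ties up to a relative epsilon so equal-probability
    # configurations are never dropped by float noise
    pvals = np.array([prob[prob <= p * (1 + 1e-12)].sum() for p in prob])
    return np.minimum(pvals, 1.0)


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact test for Hardy-Weinberg proportions.

    Sums the conditional probabilities (given the allele counts) of every
    heterozygote configuration at most as probable as the observed one.
    Monomorphic SNPs return 1 by convention.
    """
    if min(n_hom1, n_het, n_hom2) < 0 or n_hom1 + n_het + n_hom2 == 0:
        raise ValueError("genotype counts must be non-negative with total > 0")
    n_total = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_minor = min(n_a, 2 * n_total - n_a)
    if n_minor == 0:
        return 1.0
    pvals = _hwe_pvalues_all(n_minor, n_total)
    return float(pvals[(n_het - n_minor % 2) // 2])


def genotype_counts(dosages) -> tuple:
    d = np.asarray(dosages)
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def apply_qc_filters(
    genotypes: pd.DataFrame,
    sample_callrate_min: float = 0.95,
    snp_callfreq_min: float = 0.96,
    maf_min: float = 0.05,
    hwp_min: float = 0.001,
):
    """Apply the validation filters and return (filtered matrix, QCReport).

    Keeps samples with call rate > ``sample_callrate_min``; then keeps SNPs
    with call frequency > ``snp_callfreq_min``, exact-HWE p >= ``hwp_min``
    and MAF > ``maf_min`` (strict: a SNP at exactly the MAF threshold is
    discarded).
    """
    g = genotypes
    called = (g != MISSING).to_numpy()
    sample_cr = called.mean(axis=1)
    keep_samples = sample_cr > sample_callrate_min
    n_samples_removed = int((~keep_samples).sum())
    g = g.loc[keep_samples]
    called = called[keep_samples]

    snp_cf = called.mean(axis=0)
    keep_cr = snp_cf > snp_callfreq_min
    n_cr = int((~keep_cr).sum())
    g = g.loc[:, keep_cr]

    hwp = pd.Series(
        [hwe_exact_test(*genotype_counts(g[c][g[c] != MISSING])) for c in g.columns],
        index=g.columns,
    )
    keep_hwp = hwp >= hwp_min
    n_hwp = int((~keep_hwp).sum())
    g = g.loc[:, keep_hwp]

    maf = pd.Series([compute_maf(g[c]) for c in g.columns], index=g.columns)
    keep_maf = maf.fillna(0) > maf_min
    n_maf = int((~keep_maf).sum())
    g = g.loc[:, keep_maf]

    if g.shape[0] == 0 or g.shape[1] == 0:
        raise ValueError("no samples or SNPs survive QC")
    report = QCReport(
        n_samples_removed=n_samples_removed,
        n_snps_removed_callrate=n_cr,
        n_snps_removed_hwp=n_hwp,
        n_snps_removed_maf=n_maf,
        n_snps_segregating=g.shape[1],
        maf=maf[keep_maf],
        hwp_p=hwp[keep_hwp],
    )
    return g, report
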