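"""Tag-SNP selection and Bonferroni calibration of genome-wide scans.

The effective number of tests is taken to be the number of tag SNPs: a
greedy pairwise tagger picks, per chromosome, the SNP covering the most
not-yet-covered SNPs at r-squared >= 0.8, until every surviving SNP is a tag
or covered by one.  Significance thresholds are then alpha divided by the
tag count in scope (whole genome or one chromosome).

Pairwise r-squared is computed from two-locus haplotype frequencies
estimated by EM from unphased genotypes: only the double-heterozygote cell
of the 3x3 genotype table is phase-ambiguous, and EM iterates the expected
split of that cell between the coupling and repulsion phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sim import MISSING

EM_MAX_ITER = 100
EM_TOL = 1e-10


@dataclass
class TagSet:
    tags: list
    covered_by: dict               # non-tag snp -> tag snp
    r2_threshold: float
    tags_per_chrom: dict = field(default_factory=dict)

    @property
    def n_tags(self) -> int:
        return len(self.tags)


@dataclass
class SignificanceLevels:
    alpha: float
    genome_wide_p: float
    per_chromosome_p: dict


def _em_tables(tables: np.ndarray):
    """EM haplotype frequencies for a stack of 3x3 genotype-pair tables.

    ``tables[..., i, j]`` counts individuals with dosage i at locus A and j
    at locus B.  Returns frequencies (f11, f10, f01, f00) of the four
    haplotypes, each shaped like ``tables[..., 0, 0]``.
    """
    t = np.asarray(tables, dtype=float)
    n2 = 2 * t.sum(axis=(-2, -1))
    c11 = 2 * t[..., 2, 2] + t[..., 2, 1] + t[..., 1, 2]
    c10 = 2 * t[..., 2, 0] + t[..., 2, 1] + t[..., 1, 0]
    c01 = 2 * t[..., 0, 2] + t[..., 0, 1] + t[..., 1, 2]
    c00 = 2 * t[..., 0, 0] + t[..., 1, 0] + t[..., 0, 1]
    dh = t[..., 1, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = (c11 + c10 + dh) / n2
        pb = (c11 + c01 + dh) / n2
        # start from linkage equilibrium
        f11, f10 = pa * pb, pa * (1 - pb)
        f01, f00 = (1 - pa) * pb, (1 - pa) * (1 - pb)
        prev_ll = None
        for _ in range(EM_MAX_ITER):
            coup = f11 * f00
            rep = f10 * f01
            denom = coup + rep
            w = np.where(denom > 0, coup / np.where(denom > 0, denom, 1.0), 0.5)
            f11 = (c11 + dh * w) / n2
            f00 = (c00 + dh * w) / n2
            f10 = (c10 + dh * (1 - w)) / n2
            f01 = (c01 + dh * (1 - w)) / n2
            ll = np.sum(np.where(dh > 0, dh * np.log(np.where(denom > 0, denom, 1.0)), 0.0))
            if prev_ll is not None and abs(ll - prev_ll) < EM_TOL:
                break
            prev_ll = ll
    return f11, f10, f01, f00


def _r2_from_freqs(f11, f10, f01, f00):
    pa = f11 + f10
    pb = f11 + f01
    denom = pa * (1 - pa) * pb * (1 - pb)
    d = f11 - pa * pb
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, d * d / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r2, 0.0, 1.0)


def estimate_r2(dosages_a, dosages_b) -> float:
    """EM-based r-squared between two SNPs from unphased dosages.

    Monomorphic input (after removing missing values) yields 0.
    """
    a = np.asarray(dosages_a)
    b = np.asarray(dosages_b)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        raise ValueError("need at least 2 jointly called samples")
    a, b = a[ok], b[ok]
    table = np.zeros((3, 3))
    np.add.at(table, (a, b), 1)
    return float(_r2_from_freqs(*_em_tables(table)))


def r2_matrix(genotypes: pd.DataFrame) -> np.ndarray:
    """All-pairs EM r-squared for the SNPs of one chromosome."""
    x = genotypes.to_numpy()
    ind = np.stack([(x == k).astype(float) for k in range(3)])  # (3, n, m)
    tables = np.einsum("inm,jnk->mkij", ind, ind)               # (m, m, 3, 3)
    r2 = _r2_from_freqs(*_em_tables(tables))
    np.fill_diagonal(r2, 1.0)
    return r2


def select_tags(genotypes: pd.DataFrame, snpmap: pd.DataFrame, r2_threshold: float = 0.8) -> TagSet:
    """Greedy pairwise tagging per chromosome.

    Repeatedly picks the SNP covering the most uncovered SNPs at
    r2 >= ``r2_threshold`` (ties broken toward the lower map position) until
    every SNP is a tag or covered by a tag.
    """
    snpmap = snpmap.set_index("snp") if "snp" in snpmap.columns else snpmap
    tags, covered_by, per_chrom = [], {}, {}
    for chrom, grp in snpmap.loc[snpmap.index.intersection(genotypes.columns)].groupby("chrom", sort=True):
        snps = grp.sort_values("bp").index.tolist()
        sub = genotypes[snps]
        cov = r2_matrix(sub) >= r2_threshold
        uncovered = np.ones(len(snps), dtype=bool)
        chrom_tags = []
        while uncovered.any():
            gain = (cov & uncovered[None, :]).sum(axis=1)
            best = int(np.argmax(gain))  # argmax takes first max -> lower bp
            chrom_tags.append(snps[best])
            newly = cov[best] & uncovered
            for j in np.flatnonzero(newly):
                if j != best:
                    covered_by[snps[j]] = snps[best]
            uncovered &= ~cov[best]
        tags.extend(chrom_tags)
        per_chrom[chrom] = len(chrom_tags)
    return TagSet(tags=tags, covered_by=covered_by, r2_threshold=r2_threshold,
                  tags_per_chrom=per_chrom)


def bonferroni_thresholds(tagset: TagSet, alpha: float = 0.05) -> SignificanceLevels:
    """Bonferroni levels from tag counts: alpha/m genome-wide and per chromosome."""
    if tagset.n_tags == 0:
        raise ValueError("tag set is empty")
    per_chrom = {c: alpha / m for c, m in tagset.tags_per_chrom.items() if m > 0}
    return SignificanceLevels(
        alpha=alpha,
        genome_wide_p=alpha / tagset.n_tags,
        per_chromosome_p=per_chrom,
    )
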