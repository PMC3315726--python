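"""QTL region and SNP-set extraction from per-SNP scan results.

A region starts from a peak SNP that beats the 5% Bonferroni chromosome-wide
level in at least one of the two scans.  The surrounding SNP-set is the
maximal contiguous run of SNPs whose p-values fall below the chromosome's
background association level — formalized here as a low percentile of the
chromosome's p-values outside a window around the peak (the study design
judged this level by eye; the percentile rule is its deterministic
surrogate).  Sets are truncated to 24 SNPs nearest the peak; a run of fewer
than 4 SNPs collapses to a single-SNP QTL.  Multiple peaks per chromosome are
extracted iteratively with an exclusion window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import AssocResult

MIN_SET = 4
MAX_SET = 24
DEFAULT_EXCLUSION_BP = 5_000_000
DEFAULT_PERCENTILE = 5.0


@dataclass
class QtlRegion:
    chrom: int
    trait: str
    peak_snp: str
    peak_p_naive: float
    peak_p_qfam: float
    start_bp: int
    end_bp: int
    snpset: list            # ordered SNP ids; [peak] when single_snp
    single_snp: bool

    @property
    def n_snps(self) -> int:
        return len(self.snpset)


def background_level(chrom_results: pd.DataFrame, peak_bp: int,
                     exclusion_window_bp: int = DEFAULT_EXCLUSION_BP,
                     q: float = DEFAULT_PERCENTILE,
                     fallback: float | None = None) -> float:
    """Background association level of one chromosome.

    The q-th percentile of the per-SNP p-values after excluding SNPs within
    ``exclusion_window_bp`` of the peak.  With fewer than 20 SNPs left the
    chromosome-wide Bonferroni level (``fallback``) is returned instead.
    """
    away = (chrom_results["bp"] - peak_bp).abs() > exclusion_window_bp
    p = chrom_results.loc[away, "p"].dropna()
    if len(p) < 20:
        if fallback is None:
            raise ValueError("too few background SNPs and no fallback level")
        return fallback
    return float(np.percentile(p, q))


def _combined_p(table: pd.DataFrame) -> np.ndarray:
    return np.fmin(np.nan_to_num(table["p_naive"].to_numpy(), nan=1.0),
                   table["emp_p"].to_numpy())


def build_snpsets(assoc: AssocResult,
                  exclusion_window_bp: int = DEFAULT_EXCLUSION_BP,
                  q: float = DEFAULT_PERCENTILE) -> list:
    """Extract QTL regions for one breed x trait from a completed scan."""
    regions = []
    for chrom, grp in assoc.table.groupby("chrom", sort=True):
        grp = grp.sort_values("bp").reset_index(drop=True)
        grp["p"] = _combined_p(grp)
        thr = assoc.thresholds.per_chromosome_p.get(chrom)
        if thr is None:
            continue
        available = np.ones(len(grp), dtype=bool)
        while True:
            qualifying = available & grp["suggestive"].to_numpy()
            if not qualifying.any():
                break
            cand = grp.loc[qualifying]
            peak_row = cand.loc[cand["p"].idxmin()]
            peak_i = int(grp.index[grp["snp"] == peak_row["snp"]][0])
            bg = background_level(grp, peak_row["bp"], exclusion_window_bp, q,
                                  fallback=thr)
            below = grp["p"].to_numpy() < bg
            below[peak_i] = True  # peak always belongs to its own set
            lo = peak_i
            while lo > 0 and below[lo - 1] and available[lo - 1]:
                lo -= 1
            hi = peak_i
            while hi < len(grp) - 1 and below[hi + 1] and available[hi + 1]:
                hi += 1
            members = list(range(lo, hi + 1))
            if len(members) > MAX_SET:
                dist = np.abs(grp.loc[members, "bp"].to_numpy() - peak_row["bp"])
                order = np.lexsort((grp.loc[members, "bp"].to_numpy(), dist))
                members = sorted(np.asarray(members)[order[:MAX_SET]])
            single = len(members) < MIN_SET
            snpset = [peak_row["snp"]] if single else grp.loc[members, "snp"].tolist()
            first, last = (peak_i, peak_i) if single else (members[0], members[-1])
            regions.append(QtlRegion(
                chrom=chrom,
                trait=assoc.trait,
                peak_snp=peak_row["snp"],
                peak_p_naive=float(peak_row["p_naive"]),
                peak_p_qfam=float(peak_row["emp_p"]),
                start_bp=int(grp.loc[first, "bp"]),
                end_bp=int(grp.loc[last, "bp"]),
                snpset=snpset,
                single_snp=single,
            ))
            near = (grp["bp"] - peak_row["bp"]).abs() <= exclusion_window_bp
            available &= ~near.to_numpy()
            available[members] = False
    return regions


def regions_to_frame(regions: list) -> pd.DataFrame:
    """BED-like summary table of extracted regions."""
    rows = [{
        "chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
        "peak_snp": r.peak_snp, "trait": r.trait,
        "p_naive": r.peak_p_naive, "p_qfam": r.peak_p_qfam,
        "n_snps": r.n_snps, "single_snp": r.single_snp,
        "snpset": ",".join(r.snpset),
    } for r in regions]
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "peak_snp",
                                       "trait", "p_naive", "p_qfam", "n_snps",
                                       "single_snp", "snpset"])
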