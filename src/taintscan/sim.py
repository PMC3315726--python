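"""Synthetic half-sib pig populations with LD-structured SNPs and taint-like traits.

The generator emulates the design of a Danish performance-test cohort: each
breed is a set of half-sib families (one sire, several dams, 1-2 offspring
per nuclear family), genotyped on a dense SNP panel and phenotyped for the
boar-taint compounds skatole, indole, androstenone and the S/I index on the
log10 scale.  Founder haplotypes follow a first-order Markov chain along each
chromosome so that adjacent-site linkage disequilibrium is controlled by a
single correlation parameter; offspring genotypes arise by gene dropping
(Mendelian transmission with recombination).  Causal QTL are planted as
founder haplotypes over a SNP window with an additive effect on the log10
trait scale, and the full ground truth (phases, random-effect draws) is
retained for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel

TAINT_TRAITS = ("skatole", "indole", "androstenone", "si_index")
BODY_TRAITS = ("slaughter_weight", "meat_content")


@dataclass(frozen=True)
class PlantedQtl:
    """A causal haplotype planted in the founder pool.

    ``beta`` is the additive genetic effect per h-unit on the log10 trait
    scale, where h codes copies of the causal haplotype as {0,1,2} -> {-1,0,1}.
    """

    chrom: int
    snp_start: int          # index of first SNP of the window, within chrom
    snp_stop: int           # exclusive stop index, within chrom
    causal_haplotype: str   # allele string over the window, e.g. "01101"
    beta: float
    trait: str = "androstenone"

    def __post_init__(self):
        if self.snp_stop - self.snp_start < 1:
            raise ValueError("QTL window must span at least one SNP")
        if self.causal_haplotype and (
            len(self.causal_haplotype) != self.snp_stop - self.snp_start
        ):
            raise ValueError("causal haplotype length must match window")
        if self.trait not in TAINT_TRAITS + BODY_TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")


def _default_variances() -> dict:
    # log10-scale components sized so sire+dam variance gives a mid-range
    # heritability (~0.5) against a total log10 variance near 0.09
    return {
        "sire": 0.012,
        "dam": 0.012,
        "season": 0.004,
        "pen": 0.004,
        "herd": 0.004,
        "residual": 0.055,
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated breed cohort.

    Defaults mirror the largest of the three study cohorts: 71 sires mated to
    229 dams, one or two offspring per nuclear family, and log10-scale trait
    variance components compatible with published boar-taint heritabilities.
    """

    n_sires: int = 71
    n_dams: int = 229
    offspring_per_dam: int = 1
    n_snps_per_chrom: int = 100
    n_chroms: int = 3
    allele_freq_range: tuple = (0.1, 0.9)
    adjacent_ld_r: float = 0.6
    recomb_rate_per_interval: float = 0.01
    qtl_spec: tuple = ()
    variance_components: dict = field(default_factory=_default_variances)
    trait_mean_log10: float = 0.45
    n_seasons: int = 8
    n_pens: int = 20
    n_herds: int = 49
    bp_spacing: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.n_sires < 1 or self.n_dams < 1:
            raise ValueError("need at least one sire and one dam")
        if self.n_dams < self.n_sires:
            raise ValueError("pedigree requires n_dams >= n_sires")
        if self.offspring_per_dam not in (1, 2):
            raise ValueError("offspring_per_dam must be 1 or 2")
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("allele frequencies must lie in (0, 1)")
        if not (0 <= self.adjacent_ld_r < 1):
            raise ValueError("adjacent_ld_r must be in [0, 1)")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variance components must be non-negative")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimTruth:
    """Ground truth retained for validating the analysis pipeline."""

    founder_haplotypes: np.ndarray        # (2*(n_sires+n_dams), n_snps) of 0/1
    true_phases: dict                     # animal id -> (hap_pat, hap_mat) 0/1 arrays
    qtl_spec: tuple
    realized_random_effects: dict         # factor -> level draws (per trait)


# ---------------------------------------------------------------------------
# founder haplotypes

def _chrom_slices(cfg: SimConfig):
    for c in range(cfg.n_chroms):
        yield c + 1, slice(c * cfg.n_snps_per_chrom, (c + 1) * cfg.n_snps_per_chrom)


def simulate_founder_haplotypes(cfg: SimConfig, rng=None, n_haplotypes=None) -> np.ndarray:
    """Draw the founder haplotype pool as per-chromosome Markov chains.

    Each site j has a stationary allele-1 frequency p_j drawn uniformly from
    ``allele_freq_range``; adjacent sites have Pearson correlation
    ``adjacent_ld_r`` between their 0/1 allele indicators.  Chains restart at
    chromosome boundaries.  Returns an array of shape (pool, n_snps).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_hap = 2 * (cfg.n_sires + cfg.n_dams) if n_haplotypes is None else n_haplotypes
    n_snps = cfg.n_chroms * cfg.n_snps_per_chrom
    lo, hi = cfg.allele_freq_range
    r = cfg.adjacent_ld_r
    # two Bernoullis with freqs p1 <= p2 can reach correlation at most
    # sqrt(odds(p1)/odds(p2)); sample each site's frequency from the feasible
    # odds-interval of its predecessor so the requested correlation is exact
    odds = lambda p: p / (1 - p)
    inv_odds = lambda o: o / (1 + o)
    freqs = np.empty(n_snps)
    haps = np.empty((n_hap, n_snps), dtype=np.int8)
    for _, sl in _chrom_slices(cfg):
        for k, j in enumerate(range(sl.start, sl.stop)):
            if k == 0:
                p = rng.uniform(lo, hi)
            else:
                u = freqs[j - 1]
                if r > 0:
                    p_lo = max(lo, inv_odds(odds(u) * r * r))
                    p_hi = min(hi, inv_odds(odds(u) / (r * r)))
                else:
                    p_lo, p_hi = lo, hi
                if p_lo > p_hi:
                    raise ValueError(
                        "adjacent_ld_r infeasible within allele_freq_range "
                        f"(previous frequency {u:.3f})"
                    )
                p = rng.uniform(p_lo, p_hi)
            freqs[j] = p
            if k == 0:
                haps[:, j] = rng.random(n_hap) < p
                continue
            p_prev = freqs[j - 1]
            cov = r * np.sqrt(p * (1 - p) * p_prev * (1 - p_prev))
            p11 = p_prev * p + cov
            p_given1 = p11 / p_prev
            p_given0 = (p - p11) / (1 - p_prev)
            if not (0 <= p_given1 <= 1 and 0 <= p_given0 <= 1):
                raise ValueError(
                    "adjacent_ld_r infeasible for sampled allele frequencies "
                    f"(sites {j - 1}, {j}: p={p_prev:.3f}, {p:.3f})"
                )
            cond = np.where(haps[:, j - 1] == 1, p_given1, p_given0)
            haps[:, j] = rng.random(n_hap) < cond
    return haps


# ---------------------------------------------------------------------------
# pedigree

def simulate_pedigree(cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Build the half-sib pedigree: sires, dams, and their offspring.

    Each dam is mated to exactly one sire (every sire receives at least one
    dam; surplus dams are allocated uniformly at random, so half-sib family
    sizes vary) and produces ``offspring_per_dam`` offspring.  Returns a frame
    with columns ``animal, sire, dam, role`` where founders have sire/dam 0.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    sires = [f"S{i+1}" for i in range(cfg.n_sires)]
    dams = [f"D{i+1}" for i in range(cfg.n_dams)]
    rows = [(s, "0", "0", "sire") for s in sires]
    rows += [(d, "0", "0", "dam") for d in dams]
    mate = np.concatenate([
        np.arange(cfg.n_sires),
        rng.integers(0, cfg.n_sires, size=cfg.n_dams - cfg.n_sires),
    ])
    rng.shuffle(mate)
    k = 0
    for i, d in enumerate(dams):
        for _ in range(cfg.offspring_per_dam):
            k += 1
            rows.append((f"O{k}", sires[mate[i]], d, "offspring"))
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "role"])


# ---------------------------------------------------------------------------
# gene dropping

def _gamete(hap_a, hap_b, cfg, rng):
    """One recombinant gamete from a parent's ordered haplotype pair."""
    n_snps = hap_a.shape[0]
    out = np.empty(n_snps, dtype=np.int8)
    for _, sl in _chrom_slices(cfg):
        m = sl.stop - sl.start
        cur = rng.integers(0, 2)
        cross = rng.random(m - 1) < cfg.recomb_rate_per_interval
        which = np.empty(m, dtype=np.int8)
        which[0] = cur
        which[1:] = (cur + np.cumsum(cross)) % 2
        seg = np.where(which == 0, hap_a[sl], hap_b[sl])
        out[sl] = seg
    return out


def gene_drop(pedigree: pd.DataFrame, pool: np.ndarray, cfg: SimConfig, rng=None):
    """Drop founder haplotypes through the pedigree.

    Founders take consecutive haplotype pairs from the pool; each offspring
    receives one recombinant gamete per parent.  Returns ``(genotypes, truth)``
    where genotypes is a DataFrame (animals x SNPs, dosage of allele 1) and
    truth records every animal's ordered (paternal, maternal) phase.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    founders = pedigree[pedigree.role != "offspring"]
    if 2 * len(founders) > pool.shape[0]:
        raise ValueError("founder pool too small for pedigree")
    phases: dict = {}
    for i, a in enumerate(founders.animal):
        phases[a] = (pool[2 * i].copy(), pool[2 * i + 1].copy())
    for row in pedigree[pedigree.role == "offspring"].itertuples():
        pat = _gamete(*phases[row.sire], cfg, rng)
        mat = _gamete(*phases[row.dam], cfg, rng)
        phases[row.animal] = (pat, mat)
    geno = np.vstack([phases[a][0] + phases[a][1] for a in pedigree.animal])
    genotypes = pd.DataFrame(geno, index=pedigree.animal.to_numpy(), dtype=np.int8)
    truth = SimTruth(
        founder_haplotypes=pool,
        true_phases=phases,
        qtl_spec=tuple(cfg.qtl_spec),
        realized_random_effects={},
    )
    return genotypes, truth


# ---------------------------------------------------------------------------
# phenotypes

def causal_h(truth: SimTruth, qtl: PlantedQtl, animals, cfg: SimConfig) -> np.ndarray:
    """h-coding of causal-haplotype copies: {2,1,0} copies -> {1,0,-1}."""
    sl = slice(
        (qtl.chrom - 1) * cfg.n_snps_per_chrom + qtl.snp_start,
        (qtl.chrom - 1) * cfg.n_snps_per_chrom + qtl.snp_stop,
    )
    target = np.fromiter((int(c) for c in qtl.causal_haplotype), dtype=np.int8)
    h = np.empty(len(animals))
    for i, a in enumerate(animals):
        pat, mat = truth.true_phases[a]
        copies = int(np.array_equal(pat[sl], target)) + int(np.array_equal(mat[sl], target))
        h[i] = copies - 1
    return h


def simulate_phenotypes(pedigree: pd.DataFrame, truth: SimTruth, cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Generate the phenotype table for the offspring (the phenotyped boars).

    Each taint trait is built on the log10 scale as
    ``mean + beta*h + sire + dam + season + pen + herd + residual`` with
    independent Gaussian random effects at each factor level, then
    back-transformed (``10**log10``) to the raw ug/g scale, so the pipeline's
    log10 transform exactly recovers the generative scale.  Slaughter weight
    and meat content are generated on their natural scales and pick up a
    planted haplotype effect only when a PlantedQtl names them.
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    off = pedigree[pedigree.role == "offspring"].reset_index(drop=True)
    n = len(off)
    season = rng.integers(0, cfg.n_seasons, n)
    pen = rng.integers(0, cfg.n_pens, n)
    herd = rng.integers(0, cfg.n_herds, n)
    sire_codes = pd.Categorical(off.sire).codes
    dam_codes = pd.Categorical(off.dam).codes
    vc = cfg.variance_components
    tab = pd.DataFrame({
        "animal": off.animal,
        "breed": "SIM",
        "sire": off.sire,
        "dam": off.dam,
        "season": season + 1,
        "pen": pen + 1,
        "herd": herd + 1,
    })
    h_by_trait = {t: np.zeros(n) for t in TAINT_TRAITS + BODY_TRAITS}
    beta_by_trait = {t: 0.0 for t in TAINT_TRAITS + BODY_TRAITS}
    for qtl in cfg.qtl_spec:
        h_by_trait[qtl.trait] = causal_h(truth, qtl, off.animal, cfg)
        beta_by_trait[qtl.trait] = qtl.beta
    truth.realized_random_effects = {}
    for trait in TAINT_TRAITS:
        draws = {
            "sire": np.sqrt(vc["sire"]) * rng.standard_normal(sire_codes.max() + 1),
            "dam": np.sqrt(vc["dam"]) * rng.standard_normal(dam_codes.max() + 1),
            "season": np.sqrt(vc["season"]) * rng.standard_normal(cfg.n_seasons),
            "pen": np.sqrt(vc["pen"]) * rng.standard_normal(cfg.n_pens),
            "herd": np.sqrt(vc["herd"]) * rng.standard_normal(cfg.n_herds),
        }
        truth.realized_random_effects[trait] = draws
        log10_y = (
            cfg.trait_mean_log10
            + beta_by_trait[trait] * h_by_trait[trait]
            + draws["sire"][sire_codes]
            + draws["dam"][dam_codes]
            + draws["season"][season]
            + draws["pen"][pen]
            + draws["herd"][herd]
            + np.sqrt(vc["residual"]) * rng.standard_normal(n)
        )
        tab[trait] = 10.0 ** log10_y
    # body traits on their natural scales (kg, percent)
    tab["slaughter_weight"] = (
        100.0 + 2.0 * beta_by_trait["slaughter_weight"] * h_by_trait["slaughter_weight"]
        + 1.5 * rng.standard_normal(cfg.n_seasons)[season]
        + 4.0 * rng.standard_normal(n)
    )
    tab["meat_content"] = (
        60.0 + beta_by_trait["meat_content"] * h_by_trait["meat_content"]
        + 2.0 * rng.standard_normal(n)
    )
    return tab


def resolve_causal_haplotype(pool: np.ndarray, qtl: PlantedQtl, cfg: SimConfig,
                             target_freq: float = 0.3) -> PlantedQtl:
    """Pin an auto ('') causal haplotype to a segregating founder haplotype.

    Picks the founder haplotype over the QTL window whose pool frequency is
    closest to ``target_freq``, so carriers and non-carriers both exist in
    useful numbers.
    """
    if qtl.causal_haplotype:
        return qtl
    sl = slice(
        (qtl.chrom - 1) * cfg.n_snps_per_chrom + qtl.snp_start,
        (qtl.chrom - 1) * cfg.n_snps_per_chrom + qtl.snp_stop,
    )
    window = pool[:, sl]
    haps, counts = np.unique(window, axis=0, return_counts=True)
    freqs = counts / counts.sum()
    best = int(np.argmin(np.abs(freqs - target_freq)))
    chosen = "".join(str(int(a)) for a in haps[best])
    return replace(qtl, causal_haplotype=chosen)


def simulate_cohort(cfg: SimConfig):
    """Full generator: pedigree, genotypes, phenotypes and truth in one call."""
    s_hap, s_ped, s_drop, s_phen = np.random.SeedSequence(cfg.seed).spawn(4)
    pool = simulate_founder_haplotypes(cfg, rng=np.random.default_rng(s_hap))
    cfg = cfg.with_(qtl_spec=tuple(
        resolve_causal_haplotype(pool, q, cfg) for q in cfg.qtl_spec
    ))
    ped = simulate_pedigree(cfg, rng=np.random.default_rng(s_ped))
    geno, truth = gene_drop(ped, pool, cfg, rng=np.random.default_rng(s_drop))
    pheno = simulate_phenotypes(ped, truth, cfg, rng=np.random.default_rng(s_phen))
    return ped, geno, pheno, truth


def snp_map(cfg: SimConfig) -> pd.DataFrame:
    """MAP-style table (chrom, snp id, cM, bp) for the simulated panel."""
    rows = []
    for chrom, sl in _chrom_slices(cfg):
        for k in range(sl.stop - sl.start):
            rows.append((chrom, f"snp{sl.start + k + 1}", 0, (k + 1) * cfg.bp_spacing))
    return pd.DataFrame(rows, columns=["chrom", "snp", "cm", "bp"])
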