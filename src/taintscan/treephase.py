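"""Population binary-tree phasing of QTL SNP-sets.

The SNP-set's SNPs are ordered by physical position and a binary tree is
grown with one branch per allele per SNP; a root-to-leaf path is a candidate
haplotype.  Every animal that is not heterozygous at all SNPs deposits its
compatible phases into the tree: each compatible leaf counter is incremented
by 2/k, where k is the number of compatible haplotypes, so each animal
contributes exactly two chromosomes of mass.  A second pass through the tree
assigns each animal the compatible haplotype with the largest counter; the
second haplotype is the genotype minus the first.  Haplotypes with population
frequency above 1.5% are reported as true haplotypes.

The tree is stored sparsely (realized paths only): dense storage is
infeasible at the design's maximum SNP-set size of 24.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .sim import MISSING

TRUE_HAPLOTYPE_MIN_FREQ = 0.015
# animals with more ambiguous (heterozygous or missing) sites than this do
# not enter tree construction — a computational guard generalizing the
# exclusion of all-heterozygote animals; they are phased post hoc against
# realized paths, exactly like all-heterozygous animals
MAX_AMBIGUOUS_SITES = 12


def _as_genotype(g) -> tuple:
    return tuple(int(v) for v in np.asarray(g))


def enumerate_compatible(genotype) -> list:
    """All haplotype strings consistent with a genotype over the SNP-set.

    Homozygous sites force an allele; heterozygous and missing sites open
    both branches, so the count is 2**(h+m) for h het and m missing sites.
    """
    options = []
    for d in _as_genotype(genotype):
        if d == 0:
            options.append("0")
        elif d == 2:
            options.append("1")
        elif d == 1 or d == MISSING:
            options.append("01")
        else:
            raise ValueError(f"invalid dosage {d}")
    return ["".join(alleles) for alleles in product(*options)]


def _complement(hap: str, genotype: tuple) -> str | None:
    """Second phase implied by subtracting ``hap`` from the genotype.

    Missing sites are unconstrained and returned as '.'; an inconsistent
    subtraction (hom site not matching) returns None.
    """
    out = []
    for a, d in zip(hap, genotype):
        if d == MISSING:
            out.append(".")
            continue
        b = d - int(a)
        if b not in (0, 1):
            return None
        out.append(str(b))
    return "".join(out)


def _matches(hap: str, pattern: str) -> bool:
    return all(p == "." or p == a for a, p in zip(hap, pattern))


@dataclass
class HaplotypeTree:
    """Sparse leaf-counter view of the population binary tree."""

    n_snps: int
    counters: dict = field(default_factory=dict)   # haplotype string -> weight
    n_animals_included: int = 0

    def counter(self, hap: str) -> float:
        return self.counters.get(hap, 0.0)

    def leaves(self):
        return sorted(self.counters.items())

    def best_compatible(self, genotype, pattern: str | None = None):
        """Realized haplotype with max counter compatible with the genotype.

        ``pattern`` (alleles with '.' wildcards) further constrains the
        search.  Ties break toward the lexicographically smallest haplotype.
        Returns (hap, counter) or (None, 0.0) if no realized leaf fits.
        """
        geno = _as_genotype(genotype)
        best, best_w = None, -1.0
        for hap, w in self.counters.items():
            ok = all(
                d == MISSING or (d == 1) or (int(a) * 2 == d)
                for a, d in zip(hap, geno)
            )
            if ok and pattern is not None:
                ok = _matches(hap, pattern)
            if ok and (w > best_w or (w == best_w and (best is None or hap < best))):
                best, best_w = hap, w
        return (best, best_w) if best is not None else (None, 0.0)


def is_all_heterozygous(genotype) -> bool:
    g = _as_genotype(genotype)
    return all(d == 1 for d in g)


def _n_ambiguous(genotype) -> int:
    return sum(d in (1, MISSING) for d in _as_genotype(genotype))


def _lex_smallest_compatible(genotype) -> str:
    """Lexicographically smallest compatible haplotype, without enumeration."""
    return "".join("1" if d == 2 else "0" for d in _as_genotype(genotype))


def build_tree(genotypes: pd.DataFrame,
               max_ambiguous: int = MAX_AMBIGUOUS_SITES) -> HaplotypeTree:
    """Grow the population tree from all non-all-heterozygous animals.

    Animals with more than ``max_ambiguous`` heterozygous-or-missing sites
    are also left out (their 2^h compatible paths are uninformative and
    enumeration is infeasible for wide SNP-sets); they are phased post hoc.
    """
    if genotypes.shape[1] == 0:
        raise ValueError("empty SNP-set")
    tree = HaplotypeTree(n_snps=genotypes.shape[1])
    for _, row in genotypes.iterrows():
        geno = _as_genotype(row)
        if is_all_heterozygous(geno) or _n_ambiguous(geno) > max_ambiguous:
            continue
        compat = enumerate_compatible(geno)
        w = 2.0 / len(compat)
        for hap in compat:
            tree.counters[hap] = tree.counters.get(hap, 0.0) + w
        tree.n_animals_included += 1
    return tree


def phase_animal(genotype, tree: HaplotypeTree):
    """Most probable phase pair for one animal given the population tree.

    hap1 is the compatible haplotype with maximal counter (ties toward the
    lexicographically smallest); hap2 is the genotype minus hap1 at called
    sites, with missing sites resolved toward the highest-counter realized
    completion.  Returns ``(hap1, hap2, flag)``; the flag records whether the
    pair was resolved from realized tree paths.
    """
    geno = _as_genotype(genotype)
    hap1, w1 = tree.best_compatible(geno)
    flag = "tree-phased"
    if hap1 is None:
        hap1 = _lex_smallest_compatible(geno)
        flag = "unresolved"
    pattern = _complement(hap1, geno)
    hap2, w2 = tree.best_compatible(geno, pattern=pattern)
    if hap2 is None:
        # fall back: missing sites copy hap1's branch allele
        hap2 = "".join(a1 if p == "." else p for a1, p in zip(hap1, pattern))
        if flag == "tree-phased":
            flag = "hap2-off-tree"
    return hap1, hap2, flag


def _phase_from_leaves(genotype, tree: HaplotypeTree, flag: str):
    """Post-hoc phase from realized paths only (no enumeration).

    Used for animals left out of tree construction (all-heterozygous or too
    ambiguous): chooses the genotype-compatible complementary pair maximizing
    the product of counters over realized paths; ties break
    lexicographically.  Returns hap1 as the higher-counter member.
    """
    geno = _as_genotype(genotype)
    best_pair, best_score = None, -1.0
    for hap, w in tree.leaves():
        comp = _complement(hap, geno)
        if comp is None or "." in comp:
            continue
        score = w * tree.counter(comp)
        pair = tuple(sorted((hap, comp)))
        if score > best_score or (score == best_score and (best_pair is None or pair < best_pair)):
            best_pair, best_score = pair, score
    if best_pair is None:
        hap = _lex_smallest_compatible(geno)
        comp = _complement(hap, geno)
        comp = "".join(a if c == "." else c for a, c in zip(hap, comp))
        return hap, comp, "unresolved"
    a, b = best_pair
    if tree.counter(b) > tree.counter(a):
        a, b = b, a
    return a, b, flag


@dataclass
class PhaseAssignment:
    animal: str
    hap1: str
    hap2: str
    flag: str


@dataclass
class HaplotypeCatalog:
    frequencies: dict           # haplotype -> proportion of 2N chromosomes
    counts: dict
    true_haplotypes: list       # frequency > 1.5%, most frequent first
    coverage_percent: float     # chromosomes carrying a true haplotype
    n_chromosomes: int


def phase_population(genotypes: pd.DataFrame, tree: HaplotypeTree | None = None):
    """Phase every animal and summarize the population haplotype catalog."""
    if tree is None:
        tree = build_tree(genotypes)
    assignments = []
    for animal, row in genotypes.iterrows():
        geno = _as_genotype(row)
        if is_all_heterozygous(geno):
            h1, h2, flag = _phase_from_leaves(geno, tree, "all-het-phased")
        elif _n_ambiguous(geno) > MAX_AMBIGUOUS_SITES:
            h1, h2, flag = _phase_from_leaves(geno, tree, "ambiguous-phased")
        else:
            h1, h2, flag = phase_animal(geno, tree)
        assignments.append(PhaseAssignment(str(animal), h1, h2, flag))
    counts: dict = {}
    for a in assignments:
        for h in (a.hap1, a.hap2):
            counts[h] = counts.get(h, 0) + 1
    n_chrom = 2 * len(assignments)
    freqs = {h: c / n_chrom for h, c in counts.items()}
    true_haps = sorted(
        (h for h, f in freqs.items() if f > TRUE_HAPLOTYPE_MIN_FREQ),
        key=lambda h: (-freqs[h], h),
    )
    covered = sum(counts[h] for h in true_haps)
    catalog = HaplotypeCatalog(
        frequencies=freqs,
        counts=counts,
        true_haplotypes=true_haps,
        coverage_percent=100.0 * covered / n_chrom,
        n_chromosomes=n_chrom,
    )
    return assignments, catalog


def assignments_to_frame(assignments) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.animal, a.hap1, a.hap2, a.flag) for a in assignments],
        columns=["animal", "hap1", "hap2", "flag"],
    )
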