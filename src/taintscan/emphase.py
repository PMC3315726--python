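"""Full-likelihood EM phasing for small SNP windows.

Maximum-likelihood haplotype frequency estimation from unphased multi-locus
genotypes under Hardy-Weinberg random pairing: every compatible ordered
haplotype pair of each genotype is weighted by the product of current
frequency estimates, and frequencies are re-estimated from the expected
chromosome counts.  Exhaustive over the 2^L haplotype space, so intended for
windows of up to ~10 SNPs — which is exactly the scale of QTL SNP-sets.
Serves as the independent full-likelihood benchmark for the binary-tree
phasing algorithm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .treephase import _as_genotype, _complement, enumerate_compatible


def em_haplotype_frequencies(genotypes: pd.DataFrame, max_iter: int = 500,
                             tol: float = 1e-10) -> dict:
    """ML haplotype frequencies over a small SNP window.

    Returns a dict haplotype string -> frequency (over 2N chromosomes).
    Missing genotypes are not supported; the window must be complete.
    """
    rows = [
        _as_genotype(r) for _, r in genotypes.iterrows()
    ]
    if any(d not in (0, 1, 2) for g in rows for d in g):
        raise ValueError("EM oracle requires complete genotypes")
    # group identical genotypes
    from collections import Counter
    geno_counts = Counter(rows)
    # per distinct genotype: ordered pairs (hap index, partner index)
    hap_index: dict = {}

    def idx(h):
        if h not in hap_index:
            hap_index[h] = len(hap_index)
        return hap_index[h]

    geno_pairs = []
    for g, cnt in geno_counts.items():
        pairs = []
        for h in enumerate_compatible(g):
            partner = _complement(h, g)
            pairs.append((idx(h), idx(partner)))
        geno_pairs.append((cnt, pairs))
    m = len(hap_index)
    f = np.full(m, 1.0 / m)
    n_chrom = 2 * sum(geno_counts.values())
    prev = None
    for _ in range(max_iter):
        counts = np.zeros(m)
        ll = 0.0
        for cnt, pairs in geno_pairs:
            w = np.array([f[i] * f[j] for i, j in pairs])
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(pairs), 1.0 / len(pairs))
                tot = 1.0
            else:
                ll += cnt * np.log(tot)
                w = w / tot
            for (i, j), wk in zip(pairs, w):
                counts[i] += cnt * wk
                counts[j] += cnt * wk
        f = counts / n_chrom
        if prev is not None and abs(ll - prev) < tol:
            break
        prev = ll
    inv = {v: k for k, v in hap_index.items()}
    return {inv[i]: float(f[i]) for i in range(m) if f[i] > 0}


def total_variation_distance(freqs_a: dict, freqs_b: dict) -> float:
    """TV distance between two haplotype frequency distributions."""
    keys = set(freqs_a) | set(freqs_b)
    return 0.5 * sum(abs(freqs_a.get(k, 0.0) - freqs_b.get(k, 0.0)) for k in keys)
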