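"""Validation metrics against simulated truth: switch error, reconstruction."""

from __future__ import annotations

import numpy as np

from .sim import MISSING


def switch_error_rate(true_pairs: dict, inferred_pairs: dict) -> float:
    """Switch error of inferred phases against the true diplotypes.

    ``true_pairs`` and ``inferred_pairs`` map animal -> (hap_a, hap_b) allele
    strings (or 0/1 arrays) over the same SNP window.  At each animal's
    heterozygous sites, the inferred first haplotype is tracked against the
    true parental origin; each flip between adjacent het sites is one switch.
    Animals with fewer than two het sites contribute no opportunities.
    """
    switches = 0
    opportunities = 0
    for animal, (t1, t2) in true_pairs.items():
        i1, _ = inferred_pairs[animal]
        t1 = np.asarray([int(c) for c in t1]) if isinstance(t1, str) else np.asarray(t1)
        t2 = np.asarray([int(c) for c in t2]) if isinstance(t2, str) else np.asarray(t2)
        i1 = np.asarray([int(c) for c in i1]) if isinstance(i1, str) else np.asarray(i1)
        het = t1 != t2
        if het.sum() < 2:
            continue
        origin = (i1[het] == t1[het]).astype(int)
        switches += int(np.abs(np.diff(origin)).sum())
        opportunities += het.sum() - 1
    if opportunities == 0:
        return 0.0
    return switches / opportunities


def genotype_reconstruction_ok(genotypes, assignments) -> float:
    """Fraction of (animal, called SNP) cells where hap1+hap2 equals dosage."""
    ok = 0
    total = 0
    lookup = {a.animal: (a.hap1, a.hap2) for a in assignments}
    for animal, row in genotypes.iterrows():
        h1, h2 = lookup[str(animal)]
        for a1, a2, d in zip(h1, h2, row):
            if d == MISSING:
                continue
            total += 1
            ok += int(int(a1) + int(a2) == int(d))
    return ok / total if total else 1.0
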