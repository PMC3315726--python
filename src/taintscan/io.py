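"""Text-format I/O: PLINK PED/MAP, phenotype CSV, truth files.

Genotypes are exchanged in PLINK's original text format: one PED line per
animal (family id, individual id, sire, dam, sex, phenotype, then two allele
columns per SNP; '0 0' marks a missing genotype) and a MAP line per SNP
(chromosome, SNP id, cM, bp).  On reading, alleles are recoded to the dosage
of the lexicographically first allele observed at each SNP.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .sim import MISSING


def write_plink(genotypes: pd.DataFrame, snpmap: pd.DataFrame,
                pedigree: pd.DataFrame, prefix, breed: str = "SIM") -> None:
    """Write a cohort as <prefix>.ped / <prefix>.map.

    Internal allele 1 is written as allele label '1' and internal allele 0 as
    '2', so the lexicographically first label recovers the internal dosage on
    re-reading.  Heterozygotes are written as '1 2'.
    """
    prefix = Path(prefix)
    ped_idx = pedigree.set_index("animal")
    code = {0: ("2", "2"), 1: ("1", "2"), 2: ("1", "1"), MISSING: ("0", "0")}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for animal, row in genotypes.iterrows():
            sire, dam = ped_idx.loc[animal, ["sire", "dam"]]
            cells = [breed, str(animal), str(sire), str(dam), "1", "-9"]
            for d in row:
                cells.extend(code[int(d)])
            fh.write(" ".join(cells) + "\n")
    with open(prefix.with_suffix(".map"), "w") as fh:
        for r in snpmap.itertuples(index=False):
            fh.write(f"{r.chrom} {r.snp} {getattr(r, 'cm', 0)} {r.bp}\n")


def read_plink(ped_path, map_path):
    """Read PED/MAP into (genotypes, snpmap, pedigree).

    Genotype dosages count the lexicographically first allele label seen at
    each SNP; '0 0' pairs become the missing sentinel.  An unsorted MAP is
    stably sorted by (chrom, bp) with a warning.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{lineno}: expected 4 MAP columns, got {len(parts)}")
            map_rows.append((int(parts[0]), parts[1], float(parts[2]), int(parts[3])))
    snpmap = pd.DataFrame(map_rows, columns=["chrom", "snp", "cm", "bp"])
    if snpmap["snp"].duplicated().any():
        dup = snpmap.loc[snpmap["snp"].duplicated(), "snp"].iloc[0]
        raise ValueError(f"{map_path}: duplicate SNP id {dup!r}")
    if not snpmap.sort_values(["chrom", "bp"], kind="stable").equals(snpmap):
        warnings.warn("MAP positions not sorted; applying stable (chrom, bp) sort")
        order = snpmap.sort_values(["chrom", "bp"], kind="stable").index
    else:
        order = snpmap.index
    n_snps = len(snpmap)

    ped_rows, allele_pairs = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns, got {len(parts)}"
                )
            ped_rows.append(parts[:6])
            allele_pairs.append(parts[6:])
    alleles = np.array(allele_pairs).reshape(len(ped_rows), n_snps, 2)
    dosage = np.full((len(ped_rows), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        col = alleles[:, j, :]
        called = ~(col == "0").any(axis=1)
        labels = sorted(set(col[called].ravel()))
        if not labels:
            continue
        counted = labels[0]
        dosage[called, j] = (col[called] == counted).sum(axis=1)
    animals = [r[1] for r in ped_rows]
    genotypes = pd.DataFrame(dosage, index=animals, columns=snpmap["snp"])
    # apply stable map sort to both tables
    snpmap = snpmap.loc[order].reset_index(drop=True)
    genotypes = genotypes[snpmap["snp"]]
    pedigree = pd.DataFrame(
        [(r[1], r[2], r[3]) for r in ped_rows], columns=["animal", "sire", "dam"]
    )
    pedigree["role"] = np.where(
        (pedigree.sire == "0") & (pedigree.dam == "0"), "founder", "offspring"
    )
    return genotypes, snpmap, pedigree


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(truth, animals, path) -> None:
    """True phases as CSV of allele strings, one row per animal."""
    rows = []
    for a in animals:
        pat, mat = truth.true_phases[a]
        rows.append((a, "".join(map(str, pat)), "".join(map(str, mat))))
    pd.DataFrame(rows, columns=["animal", "hap_pat", "hap_mat"]).to_csv(path, index=False)
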