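"""End-to-end per-breed orchestration of the boar-taint QTL analysis.

For each breed, in order: genotype QC -> tag-SNP selection and Bonferroni
calibration -> log10 transform and season/pen adjustment -> the two
association scans -> QTL region and SNP-set extraction -> binary-tree
phasing of each SNP-set -> haplotype (or single-SNP) mixed-model effect
estimation -> body-trait screen and covariate-adjusted refit.  Breeds are
analysed strictly separately; a failure in one breed is logged and does not
stop the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import genome_scan
from .effects import (
    anova_screen, body_trait_adjustment, fit_haplotype_model, haplotype_h,
    make_model_frame, select_focal_haplotype, single_snp_effect,
)
from .qc import apply_qc_filters
from .regions import build_snpsets, regions_to_frame
from .sim import TAINT_TRAITS, SimConfig, simulate_cohort, snp_map
from .tagging import bonferroni_thresholds, select_tags
from .treephase import phase_population

log = logging.getLogger("taintscan")


@dataclass
class RunConfig:
    """Pipeline configuration: simulated or file-based input, one seed."""

    breeds: tuple = ("SIM",)
    traits: tuple = TAINT_TRAITS
    sim: SimConfig | None = None          # simulation block, or ...
    ped_path: str | None = None           # ... PED/MAP + phenotype files
    map_path: str | None = None
    pheno_path: str | None = None
    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    r2_threshold: float = 0.8
    effect_test: str = "lrt"       # beta=0 test: "lrt" (default) or "wald"
    outdir: str | None = None

    def __post_init__(self):
        has_files = self.ped_path is not None
        if has_files == (self.sim is not None):
            raise ValueError("exactly one of sim / input paths must be given")


@dataclass
class BreedResult:
    breed: str
    qc_report: object
    tagset: object
    thresholds: object
    scans: dict = field(default_factory=dict)       # trait -> AssocResult
    regions: list = field(default_factory=list)
    effects: list = field(default_factory=list)     # per-region dicts


def _load_breed(cfg: RunConfig, breed: str, index: int):
    from .io import read_phenotypes, read_plink

    if cfg.sim is not None:
        sim_cfg = cfg.sim.with_(seed=int((cfg.seed * 1009 + index) % 2**31))
        ped, geno, pheno, truth = simulate_cohort(sim_cfg)
        pheno = pheno.assign(breed=breed)
        smap = snp_map(sim_cfg)
        geno.columns = smap["snp"]
        return geno, smap, ped, pheno, truth
    geno, smap, ped = read_plink(cfg.ped_path, cfg.map_path)
    pheno = read_phenotypes(cfg.pheno_path)
    pheno = pheno[pheno["breed"] == breed] if "breed" in pheno else pheno
    keep = pheno["animal"].astype(str).tolist()
    geno = geno.loc[[a for a in geno.index if a in keep]]
    return geno, smap, ped, pheno, None


def analyse_region(region, genotypes, pheno, trait, effect_test="lrt"):
    """Phase a region's SNP-set and estimate the focal haplotype effect."""
    from .assoc import log10_trait

    out = {"region": region, "trait": trait}
    trait_log = pd.Series(
        log10_trait(pheno[trait]), index=pheno["animal"].astype(str)
    )
    if region.single_snp:
        est = single_snp_effect(genotypes[region.peak_snp], pheno, trait,
                                test=effect_test)
        out.update(effect=est, catalog=None, assignments=None,
                   focal=None, anova_p=np.nan)
        return out
    sub = genotypes[region.snpset]
    assignments, catalog = phase_population(sub)
    try:
        focal, freq = select_focal_haplotype(catalog, assignments, trait_log)
    except LookupError:
        log.warning("region %s/%s: no true haplotypes; skipped",
                    region.chrom, trait)
        out.update(effect=None, catalog=catalog, assignments=assignments,
                   focal=None, anova_p=np.nan)
        return out
    h = haplotype_h(assignments, focal)
    h.index = sub.index  # animal order follows the genotype matrix
    data = make_model_frame(pheno, h, trait)
    out["anova_p"] = anova_screen(data["y"], data["h"])
    est = fit_haplotype_model(data, test=effect_test)
    est.focal_haplotype = focal
    est.focal_frequency = freq
    body, adjusted = body_trait_adjustment(pheno, h, trait)
    out.update(effect=est, catalog=catalog, assignments=assignments,
               focal=focal, body=body, adjusted=adjusted)
    return out


def run_breed_pipeline(cfg: RunConfig, breed: str, index: int = 0) -> BreedResult:
    geno, smap, ped, pheno, _ = _load_breed(cfg, breed, index)
    off = ped[ped.role == "offspring"]["animal"].tolist() if "role" in ped else list(geno.index)
    pheno_animals = [a for a in off if a in set(pheno["animal"].astype(str))]
    geno_off = geno.loc[pheno_animals]

    geno_qc, report = apply_qc_filters(geno_off)
    log.info("%s: QC kept %d SNPs (%s)", breed, report.n_snps_segregating,
             report.to_frame().to_dict("records"))
    tagset = select_tags(geno_qc, smap, r2_threshold=cfg.r2_threshold)
    thresholds = bonferroni_thresholds(tagset, alpha=cfg.alpha)
    log.info("%s: %d tags, genome-wide level %.3g", breed, tagset.n_tags,
             thresholds.genome_wide_p)

    result = BreedResult(breed, report, tagset, thresholds)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, index]))
    for trait in cfg.traits:
        scan_seed = int(rng.integers(2**31))
        scan = genome_scan(pheno, geno_qc, ped, smap, thresholds, trait,
                           breed=breed, n_perm=cfg.n_perm, seed=scan_seed)
        result.scans[trait] = scan
        regions = build_snpsets(scan)
        result.regions.extend(regions)
        for region in regions:
            result.effects.append(
                analyse_region(region, geno_qc, pheno, trait,
                               effect_test=cfg.effect_test))
    return result


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every breed; write report tables if cfg.outdir is set."""
    results = {}
    for i, breed in enumerate(cfg.breeds):
        try:
            results[breed] = run_breed_pipeline(cfg, breed, i)
        except Exception:
            log.exception("breed %s failed; continuing with the rest", breed)
    if cfg.outdir is not None:
        write_reports(results, cfg)
    return results


def effects_frame(result: BreedResult) -> pd.DataFrame:
    """Haplotype-statistics table: one row per confirmed region."""
    rows = []
    for item in result.effects:
        r = item["region"]
        est = item.get("effect")
        cat = item.get("catalog")
        adj = item.get("adjusted")
        rows.append({
            "breed": result.breed, "chrom": r.chrom, "trait": r.trait,
            "peak_snp": r.peak_snp, "single_snp": r.single_snp,
            "snpset_size": r.n_snps,
            "focal_haplotype": item.get("focal"),
            "focal_freq_pct": (None if est is None or est.focal_frequency is None
                               else 100 * est.focal_frequency),
            "n_haplotypes": None if cat is None else len(cat.true_haplotypes),
            "coverage_pct": None if cat is None else cat.coverage_percent,
            "significance": None if est is None else est.p_value,
            "fixed_effect_raw": None if est is None else est.raw_scale_effect,
            "variance_explained_pct": (None if est is None
                                       else 100 * est.variance_explained),
            "adjusted_effect_raw": None if adj is None else adj.raw_scale_effect,
        })
    return pd.DataFrame(rows)


def body_frame(result: BreedResult) -> pd.DataFrame:
    rows = []
    for item in result.effects:
        for body, est in (item.get("body") or {}).items():
            if est.p_value < 0.05:
                rows.append({
                    "breed": result.breed, "chrom": item["region"].chrom,
                    "trait": item["trait"], "body_trait": body,
                    "significance": est.p_value,
                    "fixed_effect": est.raw_scale_effect,
                })
    return pd.DataFrame(rows, columns=["breed", "chrom", "trait", "body_trait",
                                       "significance", "fixed_effect"])


def write_reports(results: dict, cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for breed, res in results.items():
        pd.DataFrame({"tag": res.tagset.tags}).to_csv(
            outdir / f"{breed}_tags.csv", index=False)
        (outdir / f"{breed}_thresholds.json").write_text(json.dumps({
            "alpha": res.thresholds.alpha,
            "genome_wide_p": res.thresholds.genome_wide_p,
            "per_chromosome_p": {str(k): v for k, v
                                 in res.thresholds.per_chromosome_p.items()},
        }, indent=2))
        res.qc_report.to_frame().to_csv(outdir / f"{breed}_qc.csv", index=False)
        regions_to_frame(res.regions).to_csv(outdir / f"{breed}_regions.tsv",
                                             sep="\t", index=False)
        effects_frame(res).to_csv(outdir / f"{breed}_haplotype_effects.tsv",
                                  sep="\t", index=False)
        body_frame(res).to_csv(outdir / f"{breed}_body_traits.tsv",
                               sep="\t", index=False)
        for trait, scan in res.scans.items():
            scan.table.to_csv(outdir / f"{breed}_{trait}_scan.tsv",
                              sep="\t", index=False)
    provenance = {
        "taintscan_version": __version__,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "alpha": cfg.alpha,
        "r2_threshold": cfg.r2_threshold,
        "breeds": list(cfg.breeds),
        "traits": list(cfg.traits),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
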