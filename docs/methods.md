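# Methods

`taintscan` re-implements, as a tested library, a family-based QTL analysis
for boar-taint compounds (skatole, indole, androstenone and the combined S/I
index, all in µg/g adipose tissue) in purebred pig cohorts with a half-sib
family structure. Because no genotype or phenotype data of this design are
publicly deposited, the package ships a synthetic-cohort generator that
reproduces the statistical structure the analysis assumes, and every claim
the test suite makes is a claim about that structure.

## The synthetic cohort generator

**Pedigree.** A breed cohort is `n_sires` boars mated to `n_dams` sows
(default 71 × 229, the largest of the three study-like cohorts), each dam
producing 1–2 offspring; every sire receives at least one dam and surplus
dams are allocated uniformly at random, so half-sib family sizes vary the
way test-station cohorts do. Only offspring are phenotyped.

**Founder haplotypes.** Per chromosome, founder haplotypes are first-order
Markov chains over biallelic SNPs. Site frequencies are drawn from
`allele_freq_range` and adjacent 0/1 allele indicators have Pearson
correlation `adjacent_ld_r` exactly: two Bernoulli variables with
frequencies p₁ ≤ p₂ admit correlation at most √(odds(p₁)/odds(p₂)), so each
site's frequency is sampled from the feasible odds-interval of its
predecessor. This makes frequencies autocorrelated along the chromosome
(realistic) and raises a parameterization error only for structurally
impossible configurations. A single LD parameter is deliberate: it is the
one dial the tagging, phasing and region-selection machinery responds to.

**Gene dropping.** Founders take haplotype pairs from the pool; each
offspring receives one recombinant gamete per parent with crossover
probability `recomb_rate_per_interval` (default 0.01) between adjacent
SNPs. True phases are retained (`SimTruth`) so phasing can be scored
against truth.

**Phenotypes.** Traits are generated on the log10 scale by the same model
the analysis fits: mean + β·h + sire + dam + season + pen + herd + residual,
with h ∈ {−1,0,1} counting copies of the planted causal haplotype, then
back-transformed as 10^value, so the pipeline's log10 transform exactly
recovers the generative scale. Default variance components (log10 scale):
sire 0.012, dam 0.012, season/pen/herd 0.004 each, residual 0.055 — total
≈ 0.09, giving a narrow-sense heritability near 0.5 (4·sire/total ≈ 0.53),
inside the published range for androstenone, with modest environmental
structure. Season (8 levels ≈ slaughter months), pen (20) and herd (49, the
number of nucleus breeding farms in the study design) are assigned
uniformly at random. Slaughter weight (kg) and meat content (%) are
generated on their natural scales and pick up a haplotype effect only when
one is planted, to exercise the body-trait analysis.

**Planted QTL.** A `PlantedQtl` names a chromosome, SNP window, trait and
additive effect β per h-unit. A causal haplotype given as `""` is resolved
at simulation time to the founder haplotype over the window whose pool
frequency is nearest 0.30, so it segregates with useful carrier counts.

**What the generator does not emulate:** real porcine recombination maps,
selection of boars on breeding value, genotyping batch effects,
non-Gaussian random effects, and cross-breed allele-frequency divergence.
Passing tests therefore demonstrate the machinery is correct under the
stated model, not that any particular real QTL would be found.

## Genotype QC

Per breed (never pooled), in a fixed, documented order: samples with call
rate ≤ 0.95; SNPs with call frequency ≤ 0.96; SNPs with exact
Hardy-Weinberg p < 0.001 (boundary p = 0.001 is kept); SNPs with MAF ≤ 0.05
(strict: keeping requires MAF > 0.05). Removal counts are reported per
filter and are order-dependent. The HWE test is the two-sided exact test —
the conditional law of the heterozygote count given allele counts, summing
configurations no more probable than the observed one — computed through
log-factorials with a 1e-12 relative tie guard so equal-probability
configurations are never dropped by float noise.

## Tag SNPs and Bonferroni calibration

The effective number of tests is the tag-SNP count. Pairwise r² is computed
from two-locus haplotype frequencies estimated by EM from unphased
genotypes (only the double-heterozygote cell is phase-ambiguous; EM
initializes at linkage equilibrium, 100 iterations or Δlog-likelihood
< 1e-10). Tagging is greedy and per chromosome at r² ≥ 0.8 (the standard
pairwise default): repeatedly pick the SNP covering the most uncovered
SNPs, ties toward the lower map position. Thresholds are α/m with m the tag
count in scope — genome-wide or per chromosome.

## The two association scans

Traits are log10-transformed first; raw zeros (assay-floor censoring) are
shifted to half the smallest positive value, configurable. Season and pen
are screened by one-way ANOVA at p < 0.05 and regressed out jointly when
influential.

*Scan 1 (naive total association):* per SNP, the F-test of the regression
of the adjusted trait on allele dosage, (1, n−2) df, deliberately ignoring
family structure. It is a liberal first pass; its hits are "suggestive".

*Scan 2 (family-aware max(T)):* the observed statistic is |t| from the same
regression; the null is built by permuting trait values only among
offspring of the same sire (between-family contrasts intact). Family-wise
empirical p per SNP is (1 + #{permutations whose max |t| over SNPs ≥
observed})/(n_perm + 1); ties count as exceedances. Missing dosages are
mean-imputed for this scan only. Default 10,000 permutations (100,000
available); all permutation streams derive from one seed.

A SNP is *suggestive* when either scan beats the 5% Bonferroni
chromosome-wide level. Under a polygenic null (family variance but no QTL)
the naive scan is structurally anti-conservative — trait and dosage are both
family-correlated — which is precisely why its output is only suggestive and
must be confirmed by the mixed model; family-wise error control is a claim
about the exchangeable null, and that is how the false-positive tests are
framed.

## QTL regions and SNP-sets

A region's peak must beat the chromosome-wide 5% level in at least one
scan. The surrounding SNP-set is the maximal contiguous run of SNPs with
p below the chromosome's *background level* — here an explicit percentile
rule standing in for a judgement the original procedure made by eye: the
q-th percentile (default q = 5) of the chromosome's p-values outside a 5 Mb
window around the peak, falling back to the chromosome-wide Bonferroni
level when fewer than 20 SNPs remain. Runs are truncated to the 24 SNPs
nearest the peak (ties toward lower position); runs shorter than 4 SNPs
collapse to a single-SNP QTL. Multiple peaks per chromosome are extracted
iteratively, removing each region and its exclusion window before
searching again, so regions never overlap.

## Binary-tree phasing

SNP-set phases are inferred from population haplotype frequencies, not
pedigree. A binary tree over the SNPs in map order accumulates, for every
animal not heterozygous at all SNPs, weight 2/k on each of its k compatible
root-to-leaf paths — each animal contributes exactly two chromosomes of
mass (the alternative, weight 1 per leaf, over-weights high-heterozygosity
animals). A second pass assigns each animal the compatible haplotype with
the largest counter (ties: lexicographically smallest) and obtains the
second haplotype by subtracting the first from the genotype; missing sites
are resolved toward the highest-counter realized completion and flagged.
All-heterozygous animals are phased afterwards by the complementary pair
maximizing the product of counters. Haplotypes above 1.5% frequency are
*true haplotypes*; coverage is the share of the 2N assigned chromosomes
carrying one.

Numerical/engineering choices: the tree is stored sparsely (realized paths
only — 2²⁴ dense leaves would be infeasible at the maximum SNP-set width of
24); animals with more than 12 ambiguous (heterozygous or missing) sites
are excluded from tree construction — a computational guard generalizing
the all-heterozygote exclusion, since their 2^h compatible paths are both
uninformative and unenumerable — and are phased post hoc from realized
paths like all-heterozygous animals.

**Known limitation.** The assignment rule is marginal (most frequent
compatible haplotype first), not joint. On windows in strong LD — the
regime QTL SNP-sets are selected to be in, with a handful of haplotypes
carrying most chromosomes — catalog frequencies agree with exhaustive
full-likelihood EM phasing to total-variation distance < 0.05 (benchmarked
at adjacent r = 0.9, which reproduces the observed SNP-set profile of 2–14
true haplotypes covering 59–99% of chromosomes). On weak-LD windows the
winner-take-all assignment deviates from EM (TV up to ≈ 0.26 at adjacent
r = 0.6 in our measurements), and on LD-free founder pools its switch error
is far above EM's. The tree algorithm should be used for what it was
designed for: tight, highly associated SNP-sets.

## The haplotype-effect model

On the log10 scale: Y = µ + β·h + b_sire + d_dam + s_season + p_pen +
k_herd + e, all random effects independent Gaussians, h ∈ {−1,0,1} coding
copies {0,1,2} of the focal haplotype. The printed equation's
family-specific mean would be confounded with the sire effect, so a single
global intercept is used with sire as a random effect. The focal haplotype
is the most frequent true haplotype, except that the second most frequent
is substituted when its carrier mean deviates more from the overall mean
*and* the two carrier counts differ by ≤ 25%. A one-way ANOVA across h
classes is reported as a pre-screen.

Fitting is REML over the crossed variance components (`taintscan.vcreml`):
the marginal covariance V = σ²ₑI + Σₖ σ²ₖ ZₖZₖ' is formed densely and
Cholesky-factorized per objective evaluation; the restricted (or profile)
likelihood is maximized over log-variances by L-BFGS-B with analytic
gradients. At cohort sizes (n ≈ 150–300) a fit takes tens of milliseconds;
agreement with statsmodels' MixedLM and R's lme4 is verified in the test
suite to the optimizer tolerance. The β = 0 test is a 1-df likelihood-ratio
test on ML fits (default) or a Wald test (`test="wald"`); the body-trait
*screen* uses Wald by default since it only gates a refit at α = 0.05.

Two reported quantities have no unique published definition and are
implemented under declared conventions: the raw-scale fixed effect (µg/g)
is the homozygote contrast of back-transformed expectations,
10^(µ̂+β̂) − 10^(µ̂−β̂) (for natural-scale responses simply 2β̂), and the
variance explained is β̂²·Var(h)/Var(Y). Neither can be audited against the
original tables; both are validated by parameter-recovery simulation.

Body traits: the same model is fitted with slaughter weight, then meat
content, as the response; a body trait the haplotype differentiates at
0.05 is added as a fixed covariate to a refit of the taint model, and both
the original and adjusted effects are reported. Single-SNP QTL use the same
model with h derived from copies of the most frequent allele (the sign of
β̂ therefore depends on which allele is major).

## Determinism and problem sizes

All randomness flows from one integer seed with documented substream
derivation per stage (`numpy` `SeedSequence` spawning); the same seed gives
byte-identical report files. The simulation sizes used by the test suite
and the acceptance script — cohorts of 150–460 boars, genomes of 3
chromosomes × 50–60 SNPs, 200–1,000 permutations, 10–200 replicates per
property — were chosen as the smallest designs at which each statistical
property is measurable with comfortable margins; the permutation count for
the family-aware scan is a flag (`--n-perm`) and can be raised to the
study's 100,000.
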