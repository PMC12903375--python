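# Methods

## Liability model

Disease liability is the log odds of disease: `L = β₀ + PGS + E`, where
`β₀ = logit(background_rate)` anchors the reference group (PGS = 0,
no environmental modifier), the PGS is in raw log-odds units (one PGS unit
= one log-odds unit; a z-scored display scale would divide by the
population PGS sd, but all model arithmetic stays on the raw scale), and
`E` is an optional environmental offset. Prevalence is `expit(L)`.

Additivity on the log-odds scale is exact by construction, so a variant of
effect δ has `log_odds_change = δ` identically; the package stores that
constant rather than recomputing it as a difference of two nearby floats.
Its multiplicative odds effect `e^δ` is likewise background-independent,
while the absolute odds change `e^{β₀+p}(e^δ−1)` and the prevalence change
`expit(β₀+p+δ) − expit(β₀+p)` grow with the background `p`. Two useful
monotonicity facts, both asserted in tests over dense grids: the prevalence
change is strictly increasing in `p` throughout the region where all
liabilities stay ≤ 0 (the logistic difference peaks where the two
liabilities straddle 0), and at fixed `p` it is increasing in the
background rate in that same region.

Numerics: the logistic is `scipy.special.expit` (branch-stable); inputs are
never clipped, outputs are clamped to the open-interval floating-point
limits `nextafter(0,1)` and `nextafter(1,0)` so probabilities never
saturate to exactly 0 or 1. The rare-disease approximation
`prevalence ≈ e^{β₀+p}` has relative error ≈ `e^L`, i.e. < 1e−6 for
liabilities ≤ −15.

## Genetic architectures and the synthetic-data generator

An architecture is `G` unlinked diallelic loci; genotypes are independent
Binomial(2, pᵢ) draws (Hardy–Weinberg, no linkage disequilibrium, no
genomic coordinates). Per-locus parameters are i.i.d. across loci and
across gene counts, so populations differing in `G` are matched in every
per-locus statistic:

- **Allele frequencies**: Uniform(0.05, 0.5). A bounded MAF-like band keeps
  every locus polymorphic enough to contribute variance; the lower edge
  avoids near-fixed loci whose `2p(1−p)` is ~0.
- **Effect sizes**: Normal(0, 0.1) in log-odds units. Mean zero makes the
  PGS mean invariant in `G` (risk and protective alleles balance), so gene
  count moves only the variance; sd 0.1 is a small-effect common-variant
  scale — 1000 such genes give PGS sd ≈ 0.6 log-odds units, a realistic
  complex-trait spread.
- **Epistasis**: each of the C(G,2) unordered pairs is included
  independently with probability `interaction_density` (default 0.05);
  included pairs contribute `u·g_a·g_b` with `u` ~ the same Normal(0, 0.1)
  family. Bernoulli-over-pairs is the simplest scheme in which the count of
  interaction terms, and hence the epistatic variance, grows ~G²: any fixed
  positive density yields super-linear scaling. 0.05 was chosen once as a
  sparse-epistasis level at which the epistatic excess is visible at tens
  of genes without dwarfing the additive signal.

What the generator does **not** emulate: linkage disequilibrium, realistic
site-frequency spectra, finite-sample GWAS noise in the weights, dominance,
or locus-specific annotation. Tests passing on these inputs show the
liability/selection machinery behaves as derived under independence and
Hardy–Weinberg; they do not certify behavior under LD or ascertained
effect-size estimates.

Closed forms used as oracles: `Var(PGS_additive) = Σ wᵢ²·2pᵢ(1−pᵢ)` exactly
per architecture, and `E[Var] = G·E[w²]·E[2p(1−p)]` over sampled
architectures — with the defaults, E[w²] = 0.01 and E[2p(1−p)] = 0.365,
slope 0.00365 per gene. For ≤ 12 loci an exhaustive enumeration over all
3^G genotype vectors weighted by Hardy–Weinberg probabilities provides an
independent check (additive and epistatic); the epistatic variance under
random pair inclusion has no comparably simple closed form, so its scaling
claim is checked as an ordering (ratio strictly increasing in G), not a
value.

## The variance-scaling experiment

Defaults: gene counts {10, 50, 100, 500, 1000}, 10,000 individuals, 10
replicates, sample variance with the n−1 denominator, per-gene-count mean
and standard error of the mean across replicates.

Each replicate samples a fresh architecture (replicates measure
architecture-level plus genotype-level noise; `resample_architectures=False`
instead fixes one architecture per gene count and resamples only
genotypes). The additive and epistatic modes share each replicate's loci
and genotype matrix, with the epistatic condition adding interaction terms
on that same basis: the comparison is paired, so epistatic variance ≥
additive variance holds replicate by replicate and the ratio ordering
across gene counts is not washed out by architecture noise at small G.

Seed scheme (used throughout the package): `child_seed(root, k) =
(root + k) mod (2³¹−1)`. Replicate slot `k = i·R + r` (gene-count index
`i`, replicate `r`) consumes offsets 3k, 3k+1, 3k+2 for architecture,
epistasis, and genotypes. Every experiment is bit-reproducible from its
root seed.

Density estimation of PGS distributions uses a Gaussian kernel with
Silverman's-rule bandwidth on a 512-point grid spanning the data ± 4
bandwidths; constant input is rejected as degenerate.

## Selection

Fitness is `1 − s·P(disease | β₀ + PGS + E)` with cost `s ∈ (0, 1]`:
bounded in [1−s, 1], non-linear in liability because probability saturates.
Default **soft selection** uses the disease probability directly as the
expected fitness; a **hard** mode realizes a Bernoulli disease event per
individual first. Soft is the default because it has the same expectation
with less sampling variance at the population sizes used here.

The selection coefficient of a variant at background `b` is the relative
fitness reduction of a carrier versus a matched non-carrier,
`s(b) = [f(b) − f(b+δ)]/f(b)` — a distribution over backgrounds, summarized
by mean, sd, and quantiles. In a disease with β₀ = −15 even δ = 1 gives
coefficients < 1e−4·s across backgrounds in [−4, 4] (bounded by
`s·e^{β₀+b+δ}`): effectively neutral, which is why rarity shelters
large-effect alleles from selection.

Generations follow an individual-based Wright–Fisher model: constant
population size, each offspring draws two parents with probability
proportional to fitness, and inherits at each locus one allele from each
parent (transmission probability g/2 from a parent with count g). This is
the minimal standard model realizing selection against the high-liability
tail; there is no mutation, migration, within-phase environmental noise, or
assortative mating, so fixed and lost alleles are absorbing.

## The environment-shift scenario

Three phases — baseline, shifted, relaxed — with environmental offsets
(0, `shift_offset`, 0). Defaults: 100 genes (default distributions), 5,000
individuals, (10, 50, 10) generations, shift 2.0 log-odds units, s = 0.5,
background rate 0.01. The trajectory records, per generation, the mean
genetic liability (mean PGS), the prevalence under that phase's
environment, and all allele frequencies; generation 0 is the founding
population. During the shift, elevated disease probability strengthens
selection against high-PGS individuals; when the environment relaxes, the
allele-frequency changes persist, leaving end-of-phase-3 mean liability
below end-of-phase-1 — at these defaults by ~0.5–0.8 log-odds units,
reproduced in ≥ 8 of 10 replicate seeds (the claim is an ordering, not a
calibrated magnitude; the timescales and shift size are illustrative
configuration, not estimates).

## Problem sizes and runtime choices

The test suite runs the variance experiment at its default scale (gene
counts to 1000, 10,000 individuals, 10 replicates; ≈1 minute) and ten
default-scale scenario replicates (≈40 s); unit tests use smaller
populations sized so that Monte-Carlo tolerances (quoted per test from
binomial/drift standard errors, typically 3–5σ) keep false failures rare.
Bit-reproducibility is asserted by rerunning moderate-size experiments and
comparing output bytes.

## Known limitations

- No linkage, mutation, or demography: allele-frequency dynamics are pure
  selection + drift on standing variation.
- Epistatic architectures are scored exactly but their variance is
  validated only against enumeration (small G) and ordering properties
  (large G).
- The PGS is the true genetic liability — there is no estimation error, so
  background-dependence results are upper bounds on what an estimated score
  would show.
- Selection acts through a single disease with a single fitness cost; no
  pleiotropy or balancing selection.
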