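# Methods

This note documents the models, estimators, defaults and numerical
choices behind `fragdiv`, and what the synthetic-data experiments do and
do not establish.

## Data model

Genotypes are diploid, multi-allelic, integer-coded per locus
(`GenotypeMatrix`): allele pairs are stored unordered, missing calls are a
sentinel on both members of the pair, and every individual belongs to
exactly one population, every population to one region. Three marker
kinds constrain interpretation: `ssr_length` codes are repeat lengths
(allele-size statistics allowed), `ssr_id` codes are arbitrary sequence
identities (length statistics refused), `snp` loci are biallelic with
REF/ALT base labels. Genepop files are written with 3-digit alleles
(2-digit accepted on read, auto-detected per file, `000…` = missing);
population identifiers ride in the individual labels as
`population:individual` since the dialect has no population-name field.
The VCF dialect is the minimal 4.2 subset (GT only), and the TSV table is
`individual`, `population`, then `a1/a2` columns. Regions and marker
kinds are not carried by Genepop/VCF; they are supplied on read or from
the population-metadata table.

## Diversity statistics

* **Allelic richness** uses hypergeometric rarefaction on gene copies,
  computed with log-binomial coefficients (exact to ~1e-12; verified
  against exhaustive subsample enumeration for all configurations up to
  12 copies). The reporting standard is g = 40 gene copies (20 diploid
  individuals), configurable.
* **Expected heterozygosity** is Nei's unbiased estimator with n in gene
  copies; per-population values are unweighted means over loci.
* **F_IS** is 1 − H_obs/H_e per locus; the population mean weights loci
  by the number of individuals genotyped. Monomorphic loci are undefined
  and skipped.
* **F_ST** is Weir–Cockerham (1984) θ with variance components a, b, c
  summed over alleles and loci (ratio of sums). Default screens mirror
  survey practice: <25% missing data, data in every population, pooled
  minor-allele frequency >0.05 (MAF for multi-allelic loci is the
  frequency mass off the most common allele). Negative θ estimates are
  retained except when linearized. Permutation p-values shuffle
  individuals across populations (default 10,000 iterations,
  p = (1+#{θ* ≥ θ})/(1+N)).
* **Mantel tests** correlate upper-triangle linearized F_ST with
  (optionally log) great-circle distance (haversine, R = 6371 km); the
  one-sided p-value uses the same add-one convention, with an exhaustive
  mode that enumerates all n! permutations for small n. Region summaries
  exclude populations with fewer than five individuals, a rule the
  synthetic fixture deliberately exercises with one- and two-plant
  populations.

## Maximum-likelihood local F_ST

The Balding–Nichols model treats a population's allele frequencies as
Dirichlet-distributed around the regional mean π with concentration
(1−F)/F; integrating them out gives the Dirichlet-multinomial likelihood
of the focal allele counts. The implementation evaluates the summed
log-likelihood over loci in vectorized form, locates the maximum on a
200-point log-spaced grid over F ∈ [1e-4, 0.999], and refines with
bounded scalar minimization to |ΔF| < 1e-6; boundary maxima are flagged.
For biallelic loci the likelihood was checked against numerical
integration of binomial × Beta to below 1e-8 across F ∈ [0.01, 0.9].

Open design points, resolved as follows:

* The regional mean defaults to **pooled gene copies with the focal
  population included** (its literal reading); `pop_mean` weighting and
  focal exclusion are exposed for sensitivity. With few populations the
  pooled mean is partly self-referential, biasing F̂ downward by roughly
  1/(number of populations); the recovery experiment therefore uses a
  12-population region, where the estimator recovers F = 0.10 within
  ±0.02 in essentially all replicates.
* Focal alleles absent from the regional mean get a pseudo-count floor
  π = 1/(2N_region + k), renormalized; loci monomorphic in the region are
  excluded.
* The single-individual variant reruns the estimator on one individual's
  two gene copies per population (first by input order, or a seeded
  draw), to show the statistic is not a sample-size artifact.

## RAD-SSR calling

Rule order per individual × locus bundle of trimmed reads: (1) discard
sequences with fewer than 3 identical reads; (2) below 10 remaining reads
the call is missing; (3) one qualifying sequence → homozygote; (4) a
second qualifying sequence is accepted as a heterozygote when its count
strictly exceeds 10% of the bundle's **pre-filter** total (the denominator
choice is ours; the support filter precedes the fraction test, matching
the rule order as stated). More than two qualifying sequences: the two
highest counts win (ties broken lexicographically) and the surplus is
counted on the call. Integer allele codes are assigned per locus in order
of first appearance and never reused, so same-length different-sequence
alleles always separate. Loci with more than 40 distinct diploid
genotypes are dropped (genotypes, not allele sequences — the option to
count alleles exists); read trimming removes a fixed 7-base tail and
merges newly identical reads. The motif miner reports the longest perfect
di-nucleotide run (distinct bases, ≥5 repeats by default; interrupted
repeats are not detected) and requires presence in strictly more than 50
individuals. Clone detection groups individuals identical at every
shared locus (exact matching; a single mismatch separates them) and keeps
the first of each group.

## LD-based Ne

Burrows' composite Δ̂ = mean(xy)/2 − 2p̂q̂ over dosage vectors is squared
and normalized by [p(1−p) + (P_AA − p²)][q(1−q) + (P_BB − q²)], the
homozygote-excess-corrected denominator, making the estimator phase-free
and robust to inbreeding. The sampling expectation and the drift solution
use the random-mating weights: E(r²_S) = 1/S + 3.19/S² for S ≥ 30 (the
boundary uses this branch) and 0.0018 + 0.907/S + 4.44/S² below;
N̂e = (1/3 + √(1/9 − 2.76 r²′))/(2r²′), coefficients 0.308/2.08 for
S < 30. Non-positive r²′ → N̂e = ∞ (no drift signal); a negative
discriminant is flagged. The default MAF screen is 0.02. Multi-allelic
loci decompose into allele-vs-rest comparisons weighted by allele
frequency; S is the weighted harmonic mean of per-pair sample sizes.
An optional delete-one-locus jackknife gives a normal-theory confidence
interval on N̂e (reported unbounded when any delete-one estimate is
infinite). Census cross-validation regresses log N̂e on log census (exact
counts when known, else the geometric midpoint of the category),
excluding infinite estimates with a reported count. On Wright–Fisher data with
Ne = 50, S = 50 and 200 unlinked loci the median estimate over 20
replicates falls within [33, 75]; on independently drawn (LD-free)
genotypes the method reports no drift signal, as it should.

## Coalescent simulator and ABC

Each locus is an independent Kingman coalescent with piecewise-constant
diploid sizes and no migration (the scenarios are pure divergence trees).
Backwards in time under scenarios 1/1b: focal populations at their
current sizes until tb1, at NeBr from tb1 to t1, merging into an
ancestral focal population (NeBr) at t1, and into the root at t2; the
root persists at NeSc — Ne of the out-group lineage — since the scenario
set has no separate ancestral-size parameter (exposed as an override).
Scenario 2 instead holds the ancestral focal population at a colonization
bottleneck size from t2 to t1 with no recent bottleneck event.
Mutations: microsatellites take Poisson(μℓ) symmetric single-repeat steps
per branch from a root state of 100 repeats (floored at 1), each mutation
also minting a fresh sequence identity so the same tree yields both
length-coded and identity-coded alleles; SNP loci place one mutation
uniformly on the tree, emulating ascertained polymorphism, with
transition and transversion sets differing only in locus count.
Calibration checks: mean pairwise coalescence time matches 2Ne within
Monte-Carlo error; mean total branch length matches msprime; equilibrium
stepwise-mutation heterozygosity matches 1 − 1/√(1 + 8Neμ) (0.667 at
8Neμ = 8).

ABC follows rejection with regression corrections: statistics are
MAD-standardized (zero-MAD statistics dropped with a warning), Euclidean
distances rank simulations, the closest 1% are retained; scenario
posteriors come from multinomial logistic regression of scenario labels
on centred statistics, evaluated at the observation (falling back to
retained-count proportions when degenerate); parameter posteriors are
local-linear adjusted with Epanechnikov weights and clipped to prior
support, reported as the weighted-KDE peak and the 0.05–0.95 weighted
quantiles. Per-marker posteriors combine by multiplying kernel densities
on a common grid over the prior support (independent-evidence pooling,
renormalized); non-overlapping densities raise an error. The default
summary set per marker is mean alleles/locus, mean within-population H_e,
global θ, mean between-region pairwise θ, plus mean allele-size variance
for length-coded SSRs only. Priors default to uniform ranges
(t2 ∈ [100, 2000], t1, tb1 ∈ [10, 1000] with tb1 ≤ t1 ≤ t2 by rejection,
historic sizes ∈ [100, 10000]) and log-uniform current sizes ∈ [50, 2000]
and SSR mutation rate ∈ [1e-4, 1e-3].

The verification experiment runs at desk scale: 4 focal populations + 1
out-group, 6 diploids each, 15 length-coded SSR loci, 5000 simulations
per scenario and 20 pseudo-observed datasets (the survey-scale design
would use orders of magnitude more simulations; the machinery is
identical). Pseudo-observed truths describe a strong recent bottleneck —
historic size 5000, current sizes 50–200, tb1 ∈ [10, 50] — because that
is the contrast the scenario pair is designed to resolve; scenario 1 with
a small historic size is genuinely confusable with scenario 2, and no
amount of simulation separates observationally equivalent histories.
Under these conditions scenario 1 wins the posterior in ≥70% of
replicates and the NeBr interval covers the truth in ≥80%.

## Synthetic study fixture

The default fixture reproduces the emulated survey's design: 10
continuous-region populations (296 retained individuals + 8 clonal
duplicates) and 29 fragmented-region populations (770 + 41), totalling
1115 assayed samples of which 49 (4.4%) are clones; RAD marker sets cover
a 190-individual subset (60 + 130); marker sets have 18 length-coded SSR,
193 identity-coded SSR, 4775 transition-SNP and 3306 transversion-SNP
loci (ti:tv = 144:100). Fragmented-region drift parameters are tied to
census category (F = 0.35 / 0.12 / 0.06 / 0.03 from smallest to largest
bins, our choice of a plausible drift gradient); the continuous region
uses F = 0.02 throughout. SNP regional frequencies are drawn with minor
allele frequency ≥0.05 (ascertainment); SSR frequencies from flat
Dirichlets. Read bundles use Poisson coverage (mean 40) with an unbiased
heterozygote split (bias exposed as an option) and optional per-base
substitution error.

What the fixture does **not** emulate: linkage between loci (all loci are
independent, so LD-Ne on fixture genotypes correctly reports no drift
signal — Wright–Fisher simulations provide that ground truth), null
alleles, genotyping error models beyond uniform substitution, selection,
migration after divergence, and spatial genetic autocorrelation
(coordinates are decorative, so Mantel tests on the fixture are null
cases). Passing tests therefore establish estimator correctness under
the stated models, not robustness to these real-data complications.

## Problem sizes and determinism

Every generator and experiment takes an explicit seed and is reproducible
bit-for-bit at fixed seed; the verification suite's Monte-Carlo sizes
(10⁴ TMRCA replicates, 2000 SMM loci, 100 ML-F_ST replicates, 20
LD-Ne/ABC replicates, 5000 ABC simulations per scenario) were chosen so
each check's Monte-Carlo error is comfortably inside the asserted band
while the whole suite stays a desk-scale run on one CPU.
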