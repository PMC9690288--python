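# Methods

This note documents the models implemented in `erodescan`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Coordinate conventions

VCF positions are 1-based; BED and every internal interval are 0-based
half-open. The conversion happens exactly once, in `vcfio`. A
`GenomeLayout` carries scaffold lengths and masked intervals (repeat mask,
sex-linked scaffolds, mitogenome); its *analyzable length* — the denominator
of every genome-wide fraction — is the unmasked length of scaffolds at least
`min_scaffold_bp` (default 25 kb, the conventional cutoff below which
scaffolds contribute more artifact than signal).

## Site filtering

Retained sites satisfy, in this order of attribution: analyzable scaffold
outside the mask; site quality ≥ `min_qv` (30); distance to the nearest
indel anchor > `indel_exclusion_radius` (5 bp; the indel's VCF POS is used
as its anchor since indel extent handling is not otherwise well defined);
every sample's depth within [mean/3, 2·mean] of **that sample's** mean
coverage (low depth undercalls heterozygotes, high depth flags collapsed
repeats); no missing call (cross-sample comparisons need a shared site
set). A site failing several rules counts once, at the first — this makes
the report deterministic and its counts sum exactly to the input size.
Filtering is idempotent and each rule is individually monotone: relaxing
one threshold can only retain more sites.

## ROH calling

The caller reproduces the PLINK `--homozyg` procedure. Windows of
`window_snp` = 200 consecutive SNPs are homozygous when they contain at
most `window_het_max` = 3 heterozygous and `window_missing_max` = 5 missing
calls (the missing tolerance is not part of the published parameter set for
this procedure; 5 is a conservative default and exposed as a parameter). A
SNP belongs to a homozygous segment when at least `hit_threshold` = 5 % of
the windows covering it are homozygous; only windows fully inside the
scaffold's SNP list count, and a scaffold with fewer SNPs than one window
is evaluated against a single truncated window rather than silently
skipped. Maximal runs of qualifying SNPs are split at inter-SNP gaps
> 1000 kb and kept as ROH when they have ≥ 100 SNPs, span ≥ 100 kb, and
average at least one SNP per 50 kb. Segment extent is first to last member
SNP — the simplest defensible reading of "segment"; window extents would
inflate every boundary by up to a window. No per-segment heterozygote cap
is applied beyond the per-window rule. The caller is invariant to swapping
which homozygote label a site carries, and flipping any homozygous call to
heterozygous can only shrink the called total.

## F_ROH and age decomposition

F_ROH is summed ROH length over the analyzable length. A ROH of length
*L* Mb is dated to *g* = 100/(2 *r* *L*) generations since the haplotypes'
common ancestor, with *r* = 0.6 cM/Mb (silver fox map rate, used for the
arctic fox on life-history similarity). Segments are partitioned by length
into left-open bins (0.1, 2], (2, 8], (8, ∞) Mb — historical (~42–833
generations), intermediate (~10–42), recent (< ~10). The bin F values
partition the total exactly. The formula gives 833.3 and 10.4 generations
at the 0.1 and 8 Mb edges; the conventionally quoted "850" and "10" are
these values rounded. Measuring length in Mb rather than map distance
makes individual datings noisy; the bins, not the point estimates, are the
meaningful unit.

## Heterozygosity and the (θ, ε) likelihood

`het_per_kb` is heterozygous calls per kb of callable sequence. The
likelihood estimator works upstream of genotype calls, on per-site (ref,
alt) read counts: each site is heterozygous with probability θ and
homozygous otherwise, and each read misreports its allele with probability
ε. For a profile with *k* minor and *n − k* major reads,

    P(profile | hom) = C(n, k) · max over allele identity of ε^k (1−ε)^(n−k)
    P(profile | het) = C(n, k) · 0.5^n
    L(θ, ε) = (1−θ) P(hom) + θ P(het)

Zero-depth sites contribute nothing. This is a deliberate reduction of the
classic four-nucleotide read-profile likelihood to two alleles per site: it
keeps the identifiability structure (mismatches at homozygous sites pin
down ε; the excess of balanced profiles pins down θ) at a fraction of the
bookkeeping. θ is reported as the per-site heterozygosity probability;
N_e and μ are not separately identified and not modeled. Optimization is a
50 × 50 log-spaced grid over θ ∈ [10⁻⁶, 0.5], ε ∈ [10⁻⁶, 0.45] followed by
Nelder–Mead in log-parameter space from the grid optimum — fixed start, no
randomness, so estimates are deterministic given the profiles. Profiles
are assumed already quality-filtered upstream (mapping-quality filters live
before the VCF/profile abstraction); only depth is visible here.

## Mutational load

Annotated sites (LOW = synonymous, MODERATE = missense, HIGH = loss of
function; alt allele taken as the deleterious allele) are intersected with
the genotype matrix. For each individual, the homozygous and heterozygous
counts in each category are divided by one shared denominator: twice the
number of annotated sites genotyped in that individual, pooled across
categories. Whether the original convention pooled categories is
ambiguous; pooling keeps proportions comparable across categories and
individuals, and the denominator is recorded on every output row so any
other convention can be recovered from the counts.

## Structure and group tests

Dosages (0/1/2 alt alleles) are standardized per site to
(d − 2p̂)/√(2p̂(1−p̂)) with p̂ the sample alt frequency (monomorphic sites
dropped); the genomic relationship matrix is the site-averaged outer
product, and PCA is its eigendecomposition, with coordinates scaled by
√eigenvalue and variance fractions normalized over all positive
eigenvalues (normalizing over top-K would overstate the leading axes). No
LD pruning is applied — the method is run on all retained SNPs. Group
comparisons use the tie-corrected Kruskal–Wallis H (χ² reference, df =
k − 1; all-identical input returns H = 0, p = 1 rather than an error) and
Dunn's post hoc z on pooled mid-ranks with the standard tie term,
Holm-adjusted by default (Bonferroni available); the adjustment method is
recorded in every output.

## The synthetic-data generator

The generator produces the study conditions every recovery test runs
under. Sites are placed with geometric inter-site gaps (mean 1 kb,
matching the ~1 SNP/500 bp density of a mammalian cohort VCF after
complete-genotyping filtering, to order of magnitude). Outside planted
tracts an individual is heterozygous at each site with probability
θ_bg (default 0.25 — the fraction of *cohort SNP sites* heterozygous in one
individual, not a per-genomic-base rate) and homozygous-reference
otherwise. Planted tracts are perfectly homozygous with allele labels
drawn 50:50, so the caller must be label-invariant to recover them.

Tract lengths for a bin with representative age *g* follow the standard
coalescent expectation for IBD segments: Exponential with mean
100/(2 *r* *g*) Mb, truncated to the bin's length range by inverse-CDF
sampling. Default representative ages are (150, 25, 10) generations —
values *inside* each bin's age range. Using the oldest edge age for the
historical bin (833) would make nearly half that bin's tract mass shorter
than one 200-SNP window and hence undetectable by the caller being tested;
a bin's tracts have ages spanning the bin, and a mid-bin representative is
the faithful choice. Lengths are drawn 50 kb inside the bin edges and
tracts are placed uniformly on unmasked sequence with ≥ 100 kb separation:
a tract within caller resolution of a bin edge, or two tracts closer than
a window span, has no well-defined age class in the truth ledger, which
would make "recovery" ill-posed rather than hard. Per-bin planted length
is redrawn until within ±10 % relative of target. The truth ledger records
every tract, per-bin F as exact length arithmetic, and all generator
parameters.

Deleterious sites (counts and alt frequency p per impact category) receive
genotypes with P(hom alt) = p² + F·pq and P(het) = 2pq(1 − F) under the
population's inbreeding coefficient F, independently of planted tracts —
the two machineries answer different questions and coupling them would
confound both recovery tests. Optional structure sites receive
Hardy–Weinberg genotypes from population-specific frequencies drawn by a
Balding–Nichols model around a shared ancestral frequency, planting the
allele-frequency divergence PCA should detect. Read profiles have
Poisson(λ) depth; homozygote reads err with probability ε, heterozygote
reads pick an allele 50:50 then err (net alt probability exactly ½). All
randomness flows from one seeded generator; identical seeds give
bit-identical artifacts.

What the generator does **not** emulate: linkage disequilibrium outside
planted tracts, mutation/genotyping noise inside tracts (available as a
stress option is out of scope; tracts are clean by design to isolate
caller behavior), allele-frequency spectra at background sites, indel
realism, or pedigree structure. Passing recovery tests therefore shows the
estimators are correct under their own model assumptions — not that real
data meets those assumptions.

## Problem sizes used in the test suite

Recovery tests run on a 120 Mb three-scaffold layout at 1 kb SNP spacing
(~120 k sites per individual, 20 seeds) for ROH; 10⁵ sites × 10 seeds for
(θ, ε); 10⁴ annotated sites × 20 seeds for load direction; 10⁴ null
replicates for rank-test calibration; 500 fuzzed vectors of ≤ 2000 SNPs
for caller–oracle equivalence. These sizes give Monte-Carlo error well
inside the stated tolerances while keeping the full suite under a few
minutes on one core.

## Known limitations

* ROH lengths are physical (Mb), not genetic (cM); dating variance is
  large for individual segments.
* The (θ, ε) model ignores base-quality stratification and mapping error
  beyond the scalar ε.
* The load denominator convention is one defensible reading of an
  ambiguous definition (see above).
* The caller's truncated-window rule for short scaffolds is a documented
  choice where the reference procedure's edge behavior is unspecified.
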