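# Methods

This note documents the statistical models behind `baltkit`, the
assumptions they make, the defaults and why, and what the synthetic-data
generator does and does not emulate.

## The analysis problem

Low-coverage ancient DNA rarely supports confident diploid genotype
calls: depths of 0.1–10x, post-mortem cytosine deamination (C→T on one
strand, observed as G→A on the other) and short fragments mean that
per-site evidence is a handful of possibly damaged reads. The standard
response, implemented here, is to work with *pseudo-haploid* calls — one
uniformly drawn read per covered site — and statistics that are unbiased
or rankable under that observation model: outgroup f3 shared drift,
pairwise-mismatch diversity on panel-ascertained transversions,
least-squares projection onto a reference PCA, window-based ROH on the
rare high-coverage sample, and an explicit two-model drift test of
population continuity.

## Synthetic-data generator (`simdata`)

Allele frequencies drift along a user-specified population tree under
the Balding–Nichols model: a branch with drift coefficient `F ∈ [0, 1)`
transforms a parent frequency `p` into a Beta draw with mean `p` and
variance `F·p(1−p)` (shape parameters `p(1−F)/F`, `(1−p)(1−F)/F`).
This replaces an explicit Wright–Fisher simulation because its moments
are closed-form, which makes every generator property testable exactly;
the mapping to diffusion drift time is `F = 1 − e^(−t)`. Draws within
1e-9 of the boundary are clamped to exact fixation; ascertainment
(default: polymorphic in a 4-diploid outgroup panel) then removes
monomorphic sites, emulating SNP panels ascertained in wild congeners.
Admixture edges mix node frequencies linearly after drift.

The ancient observation model is: per-site depth ~ Poisson(λ); each
read samples one of the two chromosomes; at C/T and G/A sites a read
carrying the damage-prone allele (C, respectively G) flips with
probability δ; any read then flips to the other panel allele with
probability ε; whole sites drop out with a missingness probability.
Damage is modelled at the allele level, not on full read sequences —
sufficient because every downstream consumer sees allele counts or
intervals only. Variant tables assign transitions with probability 0.66
by default, approximating the transition excess of real SNP panels, so
transversion-restricted analyses operate on a realistic minority of
sites.

What the generator does *not* emulate: linkage disequilibrium between
sites (sites are exchangeable given the tree; the LD-pruning code is
exercised on duplicated/correlated columns instead), sequence-level
artefacts (mapping bias, fragment-length effects), reference bias, and
calibrated demographic histories for any real breed. Passing tests
therefore demonstrate correctness of the estimators under their own
assumptions, not robustness to every real-data pathology.

## Genotype handling (`geno`)

Coordinates are 1-based with inclusive endpoints everywhere. The single
internal missing code is −1; parsers translate `9` (EIGENSTRAT), `0`
alleles (PLINK text). EIGENSTRAT `.geno` stores the count of `allele1`
(the second allele column of `.snp`). Filtering follows the usual panel
hygiene: per-site missingness cap and minor-allele-frequency floor
(defaults 0.01/0.01), transition masking for damage robustness, merge by
(chrom, pos) with allele-label harmonization, dropping cross-panel
allele-set mismatches as triallelic. Strand-ambiguous A/T and C/G pairs
are never reverse-complement-guessed; they are retained and can be
masked explicitly. LD pruning is the greedy windowed procedure
(window 200 SNPs, step 25, r² > 0.4 removes the later site), with r²
computed on mean-imputed dosages.

## f3 and diversity (`stats`)

Outgroup f3 is `f3(O; A, B) = mean[(o − a)(o − b)]` over complete-case
sites, the expected shared drift of A and B since divergence from O.
No finite-sample bias correction is applied by default because the
statistic is used to *rank* candidate relatives against a fixed
(outgroup, ancient) pair, where the outgroup-heterozygosity term is
common to all comparisons; a documented flag enables the correction.

Pairwise mismatch (conditional nucleotide diversity) is the pooled
ratio of differing calls to jointly-called sites over within-group
pairs of pseudo-haploid samples, restricted by default to transversions
and optionally to panel-polymorphic sites. Under Hardy–Weinberg it
estimates `E[2p(1−p)]`, a heterozygosity proxy that needs no diploid
calls. Both "all pairs" and seeded "random pairs" policies exist.

Standard errors use a weighted delete-one block jackknife over
contiguous physical blocks (default 5 Mb — the block size is a package
choice; jackknife blocks only need to exceed the LD scale). The
weighted variance uses per-block SNP-count weights (`h_j = n/m_j`
pseudovalue form) and reduces exactly to the classical delete-one
jackknife at equal weights; both identities are tested.

## Projection PCA (`pca`)

The reference panel is standardized per site by the mean dosage and
`sqrt(p̂(1−p̂))`, mean-imputing missing dosages, and decomposed by SVD;
component signs are fixed by making each component's largest-magnitude
loading positive. Low-coverage samples are placed by solving the
normal equations restricted to their observed sites (lsq projection):
a complete-data reference individual reproduces its fit-time score to
machine precision, and the projection is unbiased in expectation under
random missingness (tested). Because out-of-sample projections shrink
toward the origin, an optional correction rescales projected scores by
per-PC factors calibrated via leave-one-out projection of reference
individuals; equivalence with any external tool's shrinkage is not
claimed, only the qualitative effect (projected and reference scores on
a common scale). Outlier-removal iterations are out of scope.

## ROH (`roh`)

The scanner mirrors the classic plink `--homozyg` heuristic with the
same parameter names and defaults (window 100 SNPs with ≤1 het and ≤10
missing; per-SNP hit fraction ≥ 0.02; segments need ≥100 SNPs, ≥500 kb,
≤50 kb/SNP density, and are split at >1 Mb gaps). Windows only form
where 100 consecutive SNPs exist; edge SNPs use the reduced number of
covering windows as their denominator; reported segments are trimmed to
start and end on homozygous calls. Optional depth filters blank
unreliable sites first, the way real ancient diploid calls are
depth-filtered (e.g. 5–28 reads) upstream. Bit-exact concordance with
plink's undocumented edge behaviour is not claimed. Note an arithmetic
consequence of the parameters: a 1 Mb segment needs SNP density better
than 1/10 kb to reach 100 SNPs, so recovery benchmarks use panels at
1 SNP/5 kb.

## Continuity test (`continuity`)

Per site, a latent ancestral derived-allele frequency `x` has a
Uniform(0, 1) prior. The modern population drifts from `x` for time
`t1` and is observed as `d` derived alleles in `n` chromosomes; the
ancient sample drifts for `t2` and is observed as `a` derived
pseudo-haploid calls of `m`. Continuity pins the ancient sample to the
modern lineage itself (`t2 = 0`); independence frees `t2`. Drift
transitions use the same Balding–Nichols Beta as the generator
(`F = 1 − e^(−t)`); the binomial sampling layer integrates the drifted
frequency analytically (beta-binomial), leaving one smooth integral
over `x`, evaluated by Gauss–Legendre quadrature of order 64 (config-
exposed). The quadrature is exact at `t = 0` whenever `n + m ≤ 127`
(polynomial integrand) and matches a 200k-point Riemann oracle to 1e-6
elsewhere; below `F = 1e-8` the binomial limit is used directly because
beta-binomial shapes beyond ~1e12 exceed `gammaln`'s usable precision.
The reported likelihood is conditional on the modern counts, `P(a | d)`,
which at `t1 = t2 = 0` reduces to the closed-form posterior-predictive
(hypergeometric-style) draw from the pooled evidence.

Both models are maximized by bounded L-BFGS-B from three deterministic
starts (the alternative also starts from the null optimum, enforcing
the nesting inequality). Because `t2` sits on its boundary under the
null, `2Δlog L` is referred to the mixture `½χ²₀ + ½χ²₁`. Measured
calibration: 5.0% false rejection at α = 0.05 over 200 simulations of
true continuity (50 modern diploids, 6 ancient calls, 5,000 sites);
power 100% at `t2 = 0.2` with 6 ancients and 50,000 sites. Counts are
aggregated to unique `(d, n)`×`(a, m)` combinations before fitting,
making the cost independent of site count.

## Read-level calls (`reads`)

Sexing compares the X mean depth to the length-weighted autosomal mean:
ratio ≥ 0.8 → female ("similar coverage"), ≤ 0.6 → male ("around
half"), otherwise indeterminate — the thresholds formalize the
qualitative rule and are reported alongside the raw ratio. Insertion
genotyping formalizes dual-reference breakpoint inspection as a
counting rule: a read is diagnostic for its reference version only if
it is anchored on both sides of the junction by ≥10 bp with ≤1 mismatch
in the overhang; these defaults deliberately disqualify a 3 bp/2-
mismatch chance alignment. One qualified read suffices for a call, but
calls backed by fewer than 3 reads are flagged low-confidence.

## Pipeline and reproducibility

Every stochastic function takes an explicit seed; the pipeline derives
per-stage seeds from one master seed via `SeedSequence` and records
them. Outputs carry no timestamps, so a fixed config yields
byte-identical files (hash-tested). Site counts are logged after every
filtering stage and are non-increasing by construction.

Problem sizes used by the test-suite benchmarks (package choices):
f3 ranking 100 replicates × 20k SNPs; damage robustness 50k sites × 6
ancients at 1x; ROH 50 individuals × 8k SNPs; continuity 200 calibration
+ 30 power simulations; PCA 90 reference individuals × ~3k sites with
100 projected replicates.

## Known limitations

- No LD in the generator, hence no realistic block-jackknife stress
  test against real linkage; block size is a convention, not estimated.
- The continuity model ignores sequencing error and residual damage in
  the ancient counts; run it on transversions polarized by an outgroup.
- PCA shrinkage calibration is leave-one-out empirical, not an
  analytic high-dimensional correction.
- The ROH scanner targets fidelity to the published parameter set, not
  to unpublished tie-breaking details of any particular plink build.
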