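# Methods

This note documents the models implemented in `namqtl`, the assumptions
behind the synthetic-data generator, the numerical choices, and the known
limitations. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## The NAM design and its simulator

A nested association mapping population crosses a single common parent to
N diverse founders and derives a RIL family from each cross by single-seed
descent. The simulator reproduces the statistical structure the analysis
relies on; its defaults mirror the maize NAM scale (26 families × 200
RILs, 10 chromosomes, 836 markers at ~1.3 cM spacing, 8 environments,
H² targets around 0.9), with a desk-scale preset (5 families × 100 RILs,
200 markers) used throughout the tests.

**Genetic map.** Marker positions are uniform per chromosome; the cM↔bp
relation is a random monotone piecewise-linear warp (8 interior anchors),
so physical and genetic distance are locally but not globally
proportional. All downstream cM↔bp conversion interpolates on this
backbone.

**Meiosis.** Crossover counts are Poisson with mean L/100 (L in cM) and
breakpoints are uniform — the Haldane model, no interference. This is the
standard neutral choice and makes two quantities analytic: residual
heterozygosity after n selfing generations from the F1 is (1/2)ⁿ (so five
generations give 96.875% homozygosity, the "~97%" regime of real NAM
RILs), and two-point recombination follows r = (1 − e^(−2d/100))/2. Both
are asserted in the suite within Monte-Carlo error. Founders are fully
inbred; residual founder heterozygosity is not modelled. The intermated
family present in the real population is treated like every other family
(map expansion affects one family and nothing in the inference stack
depends on it).

**Founder SNPs** are coded 0 for the common parent's allele and 1 for the
alternate; the common parent's own column is identically 0, so a SNP
segregates in family f exactly when founder f carries a 1. Allele
frequencies come from a configurable spectrum (default Uniform(0.05,
0.5)); SNPs monomorphic across the alternate founders are redrawn.

**Trait architectures.** Each trait carries QTL at uniform map positions
with per-founder effects drawn N(0, s²) where s is a per-category scale —
this is what lets "ear-like" categories have systematically larger effects
than "tassel-like" ones. Pleiotropy entries force shared positions between
trait pairs with effect vectors correlated at a chosen ρ (ρ=1 gives
proportional vectors). Effects are purely additive; heterozygotes carry
the mean of their two haplotype effects; there is no epistasis, matching
the additive models fitted downstream.

**Phenotypes.** Balanced line × environment tables from
y = g + env + fam×env + ε. Because line-mean H² is defined against the
line-within-family variance, the noise variances are solved against the
*within-family* genetic variance: Vfe + Vε = E · Vg_within (1−H²)/H², with
20% of the noise assigned to family×environment interaction and
environment main-effect variance set to half Vg (environment effects
cancel from line means; the value only matters for the variance-component
stage to have something to estimate). With zero QTL the trait is pure
noise at unit variance. What the generator does **not** emulate: field
design ("set") blocks, spatial trends, segregation distortion (off by
default), genotype-by-environment structure beyond family×env, and
non-additive gene action. Passing tests therefore certify the inference
machinery, not robustness to those real-data features.

## Phenotype preparation

Box-Cox fits maximise the profile log likelihood on the fixed grid
λ ∈ [−10, 10] step 0.1 (λ=0 is log, λ=1 affine-linear); the transform is
applied per configured trait, default off, since only count-scale traits
need it. Variance components use balanced-layout expected mean squares
(method of moments), truncated at zero — the simulator emits exactly
balanced tables, for which EMS matches REML in expectation, and a general
unbalanced mixed-model solver is deliberately out of scope. With one
environment the line, family×env and residual components are confounded;
the estimate is flagged and collapsed. Line BLUPs shrink the within-family
deviation by k = σ²_line/(σ²_line + σ²_ε/E) around the family mean; the
family effect is carried through unshrunk because the joint-linkage model
refits family explicitly.

## Joint linkage

The model is phenotype = mean + family + Σ QTL(marker×family) + error,
fitted to line BLUPs. All fitting happens in the family-centered space:
with the family term forced in, partial-F statistics of marker-by-family
blocks are identical after projecting phenotypes and dosages onto
within-family deviations, and the per-family columns of one block have
disjoint support, so the single-marker scan reduces to per-family
univariate projections — this makes 1000-permutation thresholds cheap.
Numerical choices:

- the marker-by-family block is tested as an F-df block, with df equal to
  the block's numerical rank (families where the marker does not segregate
  contribute nothing);
- entry and exit share the permutation threshold (the empirical
  α-quantile, `inverted_cdf`, of null minimum p-values from within-family
  permutation);
- ties in the minimum p are broken by genome order (columns are scanned in
  chromosome/cM order and strict improvement is required);
- collinear candidates (rank-0 after residualisation against the current
  basis, tolerance 1e-9 relative) are skipped;
- final effects come from the minimum-norm least-squares fit, so a family
  in which a marker is non-informative gets an effect of exactly 0,
  matching the expectation that most QTL segregate in a subset of
  families;
- reported per-QTL p-values are added-last partial F tests.

The fixed-size refit keeps the k most significant QTL (default 26, the
published convention for comparing traits with different QTL counts) and
refits all effects jointly.

## GWAS and RMIP

Each chromosome is analysed separately against residuals from a
joint-linkage model *excluding the family term and the focal chromosome's
QTL*. The family term is nonetheless refit inside the forward regression —
both steps follow the published procedure literally even though they
overlap. Thresholds are permutation-derived exactly as in joint linkage
but over single-df SNP dosage columns, computed once on the full data and
reused across subsamples (recomputing per subsample multiplies cost by the
subsample count and changes nothing detectable). Subsamples take 80% of
each family's RILs without replacement (rounded down, minimum two lines);
forward selection runs until no candidate beats the threshold, with a cap
of min(n/10, 60) terms as a numerical guard. Effects are the joint OLS
coefficients on the subsample's final model, always oriented to the
alternate (non-reference) allele; the summary effect is the median over
selecting subsamples. SNPs with RMIP < 0.05 are dropped from further
analysis by default.

## Effect architecture

Scaled effect = |effect| / (BLUP SD × H²). Two published descriptions of
this scaling disagree (divide by SD×H² versus divide by SD then multiply
by H²); the package adopts the first — the definition attached to the
headline effect-distribution comparison — and exposes the second behind
`scaling_factors(..., variant="sd_only")`. The reference-design bias
correction expands each QTL's n-vector of effects-versus-common-parent
into all C(n,2) absolute pairwise founder differences, the predicted QTL
effect in every possible biparental cross; the set is invariant to shifting
the reference point, which is the point of the correction. The diversity
panel for the BLUP SD is, in the synthetic pipeline, the founders' genetic
values; a test verifies that a much larger panel of recombinant genotypes
gives closely agreeing scaled medians. A joint-linkage QTL's "family
frequency" is implemented as the number of families whose |effect| exceeds
25% of the largest family effect at that QTL (configurable); the
definition is an interpretation, since a multi-allelic QTL has no intrinsic
carrier count.

## Pleiotropy

The critical correlation is r* = t*/√(t*² + df) with t* the two-tailed
Student-t critical value on df = n_families − 2 (≈0.4958 at p < 0.01 with
26 families). Joint-linkage route: trait A's QTL markers are refit against
trait B's BLUPs and the two per-family effect vectors are correlated at
each QTL; the trait-pair percentage is the sum of the two directional
significant fractions (range [0, 2]; self-comparison saturates at 2).
GWAS route: per-family SNP effects (a SNP contributes its median effect in
families where it segregates, 0 elsewhere — the choice that makes GWAS
vectors commensurable with the 26-length joint-linkage vectors) are
RMIP-weighted and averaged in 5 cM windows stepped by 2.5 cM; windows
where either trait's RMIP sum is below 0.10 are excluded, and the
trait-pair percentage is the fraction of qualifying windows significant.
Zero-variance vectors are skipped and counted non-significant. Edges are
labelled positive/negative/both from the signs of significant
correlations and displayed above a 10% floor.

## Prediction

ŷ = Σ RMIP × median effect × dosage over SNPs with RMIP ≥ 0.05, with an
optional family mean. RILs use projected dosages; founders use their own
0/1 SNP genotypes — the common parent, which belongs to every family,
receives the grand mean of family means when the family term is included.
Predictive ability is pooled squared Pearson correlation (a per-family
variant is a one-liner on the returned predictions); degenerate
predictions report r² = 0 with a flag.

## Enrichment

Only the top ten SNPs by RMIP per trait are used (ties by |median effect|,
then genome order). The observed statistic counts top SNPs within 0.5, 1
and 2 cM of any candidate gene (gene-counting available as an option — the
published description is ambiguous between the two); the null draws gene
sets of equal size uniformly from the annotation, by default including the
candidates themselves (the literal reading of "random genes"; exclusion is
a flag). Random genes, not random positions, because genes cluster along
the genome and positional nulls are far weaker. Empirical p =
(1 + #null ≥ observed)/(1 + n_null), floored at 1/(n_null+1). The
per-gene RMIP sum within 1 cM is reported ×100 by default and can exceed
100 where SNPs cluster.

## Projection details

Coordinates are 1-based inclusive bp, floating-point cM, half-open
[left, right) marker intervals; a SNP exactly at a marker belongs to the
interval on its right (numerically identical to taking the marker's own
value). Heterozygous flanking markers contribute expected dosage 0.5.
Imputation interpolates on genetic distance; projection interpolates on
physical distance within the interval — imputation answers "what is the
expected genotype here" (a recombination question) while projection
follows the convention of placing SNPs by physical position. The
alternative "genespace" interpolation is out of scope. Marker projection
agrees exactly with the stored-mosaic oracle wherever the enclosing
interval is non-recombinant; inside recombinant intervals it is an
approximation whose error shrinks with marker density (both properties are
tested).

## Calibration experiment

`jl_threshold_calibration` measures the familywise type-I error of the
permutation entry threshold: draw a null phenotype, derive its threshold,
and apply the first-entry scan to a batch of fresh standard-normal null
datasets; the pooled selection fraction estimates α. The experiment
averages over four independently derived thresholds (1000 permutations
each, 1000 fresh datasets total): a single threshold is an order-statistic
estimate whose conditional error fluctuates around α, and averaging
measures the procedure's unconditional error with smaller Monte-Carlo
variance. Problem sizes throughout the tests (5 × 100 RILs, 200 markers,
hundreds of SNPs) were chosen as the smallest designs in which every stage
retains its statistical behaviour.

## Known limitations

- EMS variance components require (near-)balanced tables; real unbalanced
  field data would need REML.
- The permutation scan tests marker-by-family blocks; no composite
  interval mapping, no epistasis scan, no kinship/mixed-model GWAS.
- Pleiotropy statistics detect consistent cross-family effect correlation
  only; tightly linked loci with family-consistent effects are
  indistinguishable from true pleiotropy by construction.
- With few families the effect-vector correlation test has very low
  power (critical r at 5 families is ≈0.96 at p<0.01), so desk-scale
  pleiotropy percentages are conservative.
- The simulator's phenotypes contain no field-design or spatial structure;
  conclusions about those aspects of real data are out of reach of this
  test bed.
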