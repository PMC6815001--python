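# Methods

## Model and procedure

Per-variant association Z-scores for `l` traits are collected into a
variants × traits matrix `Z_raw` (variants as rows; both axes labelled).
Under the null hypothesis that a variant has no horizontal pleiotropy, its
row is multivariate normal N(0, Σ), where Σ is the trait–trait correlation
of Z-scores. Σ absorbs everything that correlates statistics *across the
genome* — vertical pleiotropy, shared samples, shared confounding — which
is exactly the part of multi-trait signal that should not count as
per-variant pleiotropy. The pipeline is:

1. **Correlation estimation.** `Σ̃` is the Pearson correlation of the Z
   columns, computed by default over a variant subset greedily pruned to
   pairwise r² < 0.1 so LD clusters do not dominate; estimating on all
   variants is available and agrees closely on data without extreme LD.
   The matrix is symmetrized and its diagonal pinned to 1. No shrinkage is
   applied: with the default trait QC (pairwise trait r² ≤ 0.8) the
   empirical matrix is well conditioned.
2. **Whitening.** `Z = Σ̃^(−1/2) Z_raw` with the *symmetric* inverse
   square root (eigendecomposition, not Cholesky), which is the
   Mahalanobis whitening transform. Eigenvalues below
   `1e-6 × λ_max` are floored before inversion — a safety net for
   near-duplicate traits that should normally have been removed by QC; the
   flag `floored` records when it engages.
3. **Scoring.** `Pm = (100/l)·sqrt(Σ z_i²)`, `Pn = (100/l)·#{|z_i| > 2}`
   (strict inequality; 2 is the usual two-sided nominal-significance Z
   cutoff). Both are scaled to read as if measured on 100 traits, so
   studies with different trait counts are comparable.
4. **LD correction.** Each component is regressed (plain OLS) on the
   per-variant LD score ℓ over all scored variants, and only the slope
   term is subtracted: `Pm_LD = Pm − β_m ℓ`. The intercept is retained, so
   corrected scores keep the raw scale but can go slightly negative; the
   χ² statistic clamps negative scores to zero (P = 1). An alternative —
   recentering by the intercept — would shift all P values by a constant;
   the slope-only form is used because it is the form the score's
   correction is defined in.
5. **Theoretical inference.** `(l·Pm/100)² ~ χ²(l)` and
   `l·Pn/100 ~ Binomial(l, p0)` with `p0 = 2Φ(−2) = 0.04550026…` (the
   exact normal tail, not the rounded 0.045). LD-corrected trait counts
   are non-integer, so the binomial survival is continued to real k via
   the regularized incomplete beta `I_{p0}(k, l−k+1)`, which reproduces
   the exact binomial tail at integer k.
6. **Permutation (polygenicity) inference.** Each whitened trait column is
   permuted independently across variants (25 permutations by default);
   scores recomputed on permuted data — re-applying the *originally
   fitted* β with each variant's own ℓ, rather than refitting per
   permutation, so the null keeps the data's LD profile — are pooled into
   an empirical null. The empirical P of an observed score is
   `(1 + #{pooled > observed}) / (1 + N)`: strictly-greater counting with
   add-one smoothing, so the smallest attainable P is `1/(N+1)` rather
   than 0 (an exact zero would break the back-conversion to scores).
   Empirical P values are mapped back through the theoretical quantile
   functions to the corrected scores `Pm_P` / `Pn_P`.

## Study utilities

- **Trait QC** keeps traits with Bonferroni-significant heritability
  (`heritability_p < α/l`), then walks trait pairs with Z-column r² above
  a threshold (0.8) in descending r² (ties by trait id) and drops the
  lower-heritability member — deterministic and invariant to input order.
- **Clumping** is a greedy re-implementation of the standard procedure:
  repeatedly index the smallest-P unassigned variant with P ≤ 5e-8 and
  absorb unassigned variants with P ≤ 0.05, within 100 kb and r² ≥ 0.1 of
  the index. Variant pairs absent from the LD structure count as unlinked.
- **Enrichment** compares mean scores between a query category and
  reference variants sampled to match the query's MAF distribution
  (quantile bins of the reference MAF; without replacement when possible,
  flagged otherwise), using Welch's unequal-variance t-test.
- **Replication** declares a discovery locus replicated when any member
  variant is nominally significant in the replication data, and calibrates
  the chance expectation by permuting the replication study's whitened
  columns and re-measuring the replication fraction. With polygenic
  replication data that expectation can sit well above the naive α.
- **Polygenicity** per trait is `λ_GC^c = λ_GC − (intercept − 1)`:
  `λ_GC = median(z²)/median(χ²(1))` and the intercept comes from OLS of
  per-variant χ² on ℓ, whose excess over 1 estimates the confounding
  contribution to inflation. Stratified rescoring ranks traits into
  equal-size heritability classes (by a heritability proxy) and, within
  class, into equal-size λ_GC^c bins (ties by trait id, remainder to the
  last bin), then re-runs the whole pipeline per bin and emits QQ tables.
  For synthetic data the heritability proxy is `ldsc_slope × n_variants` —
  a ranking device only, standing in for a full heritability estimate.

## The synthetic-data generator

The generator emulates the statistical structure the method assumes,
with ground-truth labels for power/FPR evaluation:

- **Causal architecture.** Exactly `round(prop_pleio·n)` pleiotropic
  variants, each causal for a uniform random ν-subset of traits;
  independently per trait, `round(prop_nonpleio·n)` non-pleiotropic causal
  variants drawn from the remaining variants (overlap is forbidden by
  default so truth labels stay clean). The scenario grid crossed by the
  power study: h² ∈ {0.0002, 0.002, 0.02, 0.2}, pleiotropic fraction
  {0.1%, 1%}, non-pleiotropic fraction {0, 0.1%, 1%}, ν ∈ {10, 20}, trait
  correlation absent/present.
- **Effect sizes.** A causal (variant, trait) pair receives a latent
  standardized effect μ ~ N(0, effective_n·h²); its observed Z has
  marginal variance 1 + effective_n·h². `h2` is the per-variant
  heritability contributed to each affected trait; `effective_n` (default
  10,000) is the sample-size scale converting it into Z-score
  non-centrality. A `literal` mode instead draws causal Z directly from
  N(0, h²) — the shorthand in which the causal variance replaces the null
  variance; since h² ≤ 0.2 makes such variants *quieter* than null ones,
  the non-centrality convention is the default.
- **LD.** Variants sit in consecutive AR(1) blocks (fixed size, or a
  cycled pattern of sizes for a realistic spread of LD scores) with
  neighbour correlation ρ; observed Z = R·μ + R^{1/2}·ε per block, so a
  variant tags its neighbours' signal while null marginal variance stays
  exactly 1. LD scores `ℓ_i = Σ_j r²_ij` are computed analytically from R.
- **Trait correlation.** Optional mixing of trait columns by the Cholesky
  factor of a random factor-model correlation (Gaussian loadings on a few
  latent factors), emulating vertical pleiotropy.

What the generator does *not* emulate: real LD (long-range, MAF-dependent,
population-specific) — blocks are parametric and block-diagonal; allele
frequencies and their coupling to effect sizes; sample overlap between
traits beyond what the factor model induces; non-Gaussian effect-size
distributions. Passing tests therefore demonstrate the method's internal
calibration and power under its own assumptions, not performance on any
particular real cohort.

## Problem sizes used in the checks

The calibration and power checks run the generator's headline conditions
at 100 traits × 100,000 variants (null false positive rate of the χ² test
for Pm at α = 0.05; conservatism of the binomial test for Pn; ≥ 80% power
at h² = 0.002, 0.1% pleiotropic variants, ν = 10, effective_n = 10,000).
The polygenicity-stratification check uses 60,000 variants and 60 traits
in five rungs of 12, with per-trait causal counts
{150, 600, 2400, 9600, 38400} at fixed total signal
Σ(effective_n·h²) = 18,000 and heterogeneous LD blocks (sizes cycling
1/2/5/10/20, ρ = 0.8): the causal counts stay dense enough that the OLS
intercept of χ² on ℓ is stable (very sparse, very large effects bias it),
and the block-size mix gives ℓ enough spread to condition that regression.
The replication-null check uses 250 single-variant loci over 5,000 null
replication variants and 20 permutations; single-member loci are used
because the locus-level "any member significant" rule equals α only when
a locus has one effective member.

## Numerical choices and degenerate inputs

- Whitening with an exact identity model bypasses the matrix product and
  returns the input bit for bit.
- `inverse_sqrt` symmetrizes its output and verifies `MΣM ≈ I` to 1e-8 in
  tests; inputs asymmetric beyond 1e-8 are rejected.
- Zero-variance trait columns abort correlation estimation with the trait
  named; zero-variance LD scores abort the LD regression with an explicit
  instruction to skip the correction (the pipeline then scores raw).
- Ties: trait-pair pruning orders pairs by descending r² then trait id;
  equal heritability drops the lexicographically later trait; clumping
  breaks P ties by position then variant id; stratification breaks rank
  ties by trait id.
- Pn's threshold comparison is strict (`|z| > 2`); the boundary has
  measure zero for continuous scores.
- Score tables serialize at 10 significant digits and round-trip within
  1e-9 relative error; missing columns are written as `NA`.

## Known limitations

- The LD correction is a genome-wide linear adjustment; when score
  inflation is strongly nonlinear in ℓ (extreme, uniform LD with heavy
  polygenic signal) the slope-only subtraction can over- or under-correct
  the distribution's center. The permutation-based empirical P values are
  robust to this because the same correction is applied inside the null.
- `λ_GC^c` relies on an unweighted OLS intercept; traits whose signal is
  concentrated in a handful of very large effects give noisy, slightly
  biased intercepts. Real LD-score-regression implementations mitigate
  this with weights and outlier truncation, which are out of scope here.
- The permutation null treats variants as exchangeable within a trait
  column; residual LD among permuted variants is ignored (shared-β
  correlation is treated as negligible).
- Heritability estimation on the liability scale, real annotation
  retrieval, and genotype-panel LD estimation are deliberately out of
  scope; the corresponding inputs (trait heritability, variant categories,
  LD scores) are consumed from files or from the generator.
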