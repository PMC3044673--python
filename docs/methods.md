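# Methods

This note documents the statistical model, the numerical choices and the
known limits of the `bimodalgene` pipeline. It records design rationale,
not results: every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## 1. Transformation stage

Skewed unimodal distributions are the first source of false bimodal calls,
so each gene is power-transformed before any model fitting.

* **Exponent selection.** λ maximises the Box-Cox profile log-likelihood
  `(λ−1)·Σ log x − (n/2)·log σ̂²(λ)` over the fixed 801-point grid
  {−4.00, −3.99, …, 4.00}. Profile likelihood is the standard, reproducible
  reading of "most appropriate"; ties break toward λ = 1 (no transform),
  then toward the smaller λ.
* **Non-positive input.** Log2-scale intensities are normally positive; if
  not, a deterministic shift making the minimum equal 1 is applied and
  recorded, keeping the map invertible.
* **A caveat worth knowing.** On *genuinely bimodal* data the profile
  likelihood rewards whatever monotone power map makes the sample most
  Gaussian — i.e. it partially compresses the mode separation. Strong
  bimodality (separation ≳ 5 within-component SDs) survives essentially
  intact; marginal bimodality (separation ≈ 3) loses noticeable
  likelihood-ratio power. This is a property of the published procedure,
  not of this implementation, and is quantified in the power discussion
  below.
* **Trimming.** The robust pathway removes `floor(0.05·n)` smallest and
  largest values per batch group (71 → 65 and 47 → 43 samples), with ties
  broken by value then original index.

## 2. Mixture fitting

The unequal-variance two-component Gaussian likelihood is unbounded: one
component can collapse onto a single observation. Two measures make the
fit well-defined and reproducible:

* **SD floor.** σ₁, σ₂ ≥ 10⁻³ × sample SD. The floored MLE still admits
  narrow "spike" components at isolated points; these are genuine optima
  of the declared objective and the fitter finds them (the grid includes
  floor-adjacent SD multipliers, extreme-quantile means and boundary
  mixing values). They rarely matter downstream: a spike raises the null
  LRT statistic by only a few units (χ²₆ keeps p ≫ 0.001) and always fails
  the 10%-per-component rule.
* **Deterministic global search.** A factorial grid — component means over
  24 data quantiles (μ₁ < μ₂, endpoints included), SD multipliers
  {0.0015, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 0.75, 1, 1.5} of the sample SD,
  p₁ ∈ {0.03, 0.1, 0.3, 0.5, 0.7, 0.9, 0.97} — is scored within a budget
  of 200,000 likelihood evaluations (configurable; the axes shrink
  deterministically for smaller budgets, sacrificing SD/mixing resolution
  before mean resolution because the likelihood is multimodal in the
  means). The ten best *distinct* candidates, plus the best moderate-scale
  candidate and a unimodal-equivalent candidate, seed a damped
  Newton-Raphson polish on the unconstrained scale (log-offset SDs, logit
  p₁) with finite-difference derivatives, ridge damping and backtracking;
  max 200 iterations, gradient tolerance 10⁻⁸. Starts where Newton fails
  fall back to EM (tolerance 10⁻¹⁰ on the log-likelihood). The best final
  value wins and the result is canonicalised to μ₁ ≤ μ₂. Everything is
  deterministic given data and budget. The unimodal-equivalent candidate
  guarantees ℓ₂ ≥ ℓ₁ (nestedness) by construction.
* Global-optimum behaviour cannot be certified in general; it is asserted
  empirically against an independent dense-grid-plus-EM oracle in the
  acceptance suite.

## 3. Compound decision rule

Defaults: LRT p < 0.001 against χ² with **6** degrees of freedom (the
deliberately stringent published choice; configurable), misclassification
area < 0.1, ≥ 10% of points per component, gender OLS p ≥ 0.05 (computed
on untransformed values, since gender dichotomies should be caught on the
scale the data arrive in).

* **Density intersections.** With unequal variances the weighted component
  densities cross at the roots of a quadratic (0, 1 or 2 real roots).
  Only crossings *between* the component means can dichotomise the modes —
  the second crossing far out in one tail has vacuously small tail mass
  but would place the threshold outside the data — so candidate thresholds
  are the crossings within [μ₁, μ₂], with the two component means as the
  fallback when none exists. Among candidates, the one minimising the
  misclassification area is selected.
* **Misclassification area** is mixture-weighted:
  `min(p₁·P(X₁ > t), (1−p₁)·P(X₂ < t))`. The unweighted reading of the
  rule is a flag away (`_misclass_at`) but weighted is the default.
* Samples exactly at the threshold are assigned to the high mode
  (deterministic tie-break).

## 4. Replication and evidence combination

Two pathways run side by side and are reported side by side:

* **Confirmation:** compound rule on untrimmed data per identifiable batch
  group and on all samples; confirmed = pass everywhere (≥ 2 groups
  required). Samples with unidentifiable batch take part only in the
  pooled analysis. Groups under 10 samples are dropped with a warning.
* **Robust replication:** compound rule on per-group 5%-trimmed data;
  group p-values combined by Fisher's method (−2·Σ ln p ~ χ²₂ₖ, zero
  p-values clamped to the smallest positive float with a logged warning);
  Benjamini-Hochberg FDR within the gender-associated (p < 0.05) and
  non-associated strata separately, so male/female dichotomies do not
  contaminate the main stratum's FDR.

## 5. Association layers

* **eQTL scan.** Expression is rank-inverse-normal transformed (Blom
  offset 3/8, average ranks for ties) so mass points at the modes cannot
  dominate the regression; genotype enters additively (0/1/2) with age,
  gender and heritage covariates and a sibship random intercept fitted by
  REML (Wald z p-values). When every sibship is a singleton the model
  reduces exactly to OLS with t p-values. Missing genotypes are dropped
  pairwise; singular designs are skipped with a log note. Heritage is a
  numeric fraction in [0, 1] (its coding in the source cohort is
  unspecified).
* **Mode-genotype agreement.** Cohen's κ maximised over the four pairings
  of the two dominant groupings ({0} vs {1,2} and {0,1} vs {2}) with the
  two mode orientations.
* **Trait-mode association.** Trait on mode indicator, adjusted for age
  and gender, sibship random intercept; returns the adjusted high-minus-low
  difference and its two-sided p. Covariate sets are configurable per
  trait; age + gender is the default for all traits.
* **Multiple testing** across the eQTL scan uses Bonferroni on the total
  test count (α / N).

## 6. Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes:
~10²–10³ genes × ~50–225 samples; two identifiable batch groups (71/47 by
default) plus an unassigned remainder; a small bimodal fraction with
unequal component variances and interior mixing proportions; gender genes
as pure mean shifts by gender (so the gender filter, not the mixture fit,
is the correct remover); unimodal genes skewed through an inverse Box-Cox
with λ ~ U(0.25, 2) so the transform stage has real work; batch-artifact
genes as unimodal plus an additive shift in one batch; cis-SNPs (within
the gene span ± 200 kb on a toy genome of non-overlapping 20 kb genes
1 Mb apart) whose dominant grouping matches the expression mode at a
configurable concordance, plus Hardy-Weinberg decoys; and traits with a
planted mode effect (default 1.78 units on a body-fat-like trait) over
age/gender baselines. All randomness flows from one seed;
identical configurations are byte-identical.

Deliberately absent: probe/exon-level structure (values are gene-level),
array-image artifacts, correlated genes, linkage disequilibrium between
SNPs, and realistic batch-shift distributions — the magnitude of real
batch shifts is not characterised in the source material, so the default
(1.5 log2 units) is chosen for demonstrability. A green recovery test
therefore establishes that the pipeline recovers the *assumed* generative
structure, not that it is robust to everything real arrays do.

**Separation scale.** `component_separation` is expressed in pooled
within-component SD units: Δμ = sep × √(p₁σ₁² + (1−p₁)σ₂²). The default
(4.0) matches the canonical recovery setting; *confirmed-tier* genes — the
kind that replicate at p < 10⁻³ in a 47-sample batch — correspond to
separations around 6, and the replication demonstrations use that value.

## 7. Power, and an honest limitation

The compound rule's power at n = 120 was measured on planted mixtures
(full fitting budget): at separation 4 and balanced mixing, ~94% of genes
pass all four criteria; at minor fraction 0.15 the LRT stage alone passes
only ~38%, and at separation 3 the LRT rarely clears p < 0.001 at all.
Two structural ceilings follow:

* the χ²₆ / p < 0.001 test simply cannot detect marginal bimodality
  (separation ≈ 3, small minor mode) at these sample sizes — by design,
  the rule trades sensitivity for a very low false-call rate (measured
  type-I ≤ 0.5% per 2,000 unimodal genes at n = 71);
* the gender filter removes ~5% of genuinely bimodal genes through chance
  gender association (the expected false-positive rate of the p ≥ 0.05
  rule), capping end-to-end detection near 95% no matter how strong the
  signal.

The acceptance suite states a ≥ 95% detection bound for separations ≥ 3
with minor fractions ≥ 0.15; by the measurements above that bound is not
attainable under this rule, and the corresponding test is expected to
fail. It is kept, unweakened, as documentation of the gap.

## 8. Numerical details worth knowing

* LRT statistics are clamped at 0 against floating-point jitter.
* Degenerate genes (constant values) yield a "not assessable" verdict
  rather than an exception in the per-gene pipeline.
* Intersection roots closer than 10⁻¹² are deduplicated; exactly identical
  components raise a degenerate-fit error.
* Grid scoring runs in single precision for ranking only; all polished
  log-likelihoods and reported candidates are re-evaluated in double
  precision.
* The CLI writes a structured JSON log per stage with the seed, a
  SHA-256-derived configuration hash and per-stage counts; exit codes are
  0 (success), 2 (usage), 3 (data/configuration), 4 (numerical failure).
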