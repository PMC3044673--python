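# bimodalgene

Genome-wide detection of **bimodally expressed genes** in bulk expression
data, with batch-stratified replication and downstream genetic and
phenotypic follow-up.

Most expression analyses assume each gene's across-sample distribution is
(log-)normal. A small number of genes instead split cleanly into two
expression modes — often because a *cis* regulatory polymorphism switches
transcription between two levels. Finding them reliably is harder than it
looks: skewed unimodal genes, male/female differences, a handful of
outliers, and above all **batch effects** (an additive shift affecting the
samples processed together) all masquerade as bimodality. This package
implements a discovery pipeline that addresses each failure mode
explicitly, and a synthetic-data generator with full ground truth so every
stage is testable without access to restricted clinical data.

## The model and the decision rule

For each gene, expression values `x_1..x_n` (log2 scale) are first
Box-Cox transformed, `y = (x^λ − 1)/λ` (or `ln x` at λ = 0), with λ chosen
on a 0.01-step grid over [−4, 4] by profile likelihood, so that skewness is
not mistaken for a second mode. The transformed data are then fitted by
maximum likelihood under two nested models:

* unimodal: `y ~ N(μ, σ²)`
* bimodal: `y ~ p₁·N(μ₁, σ₁²) + (1 − p₁)·N(μ₂, σ₂²)` — note the
  **unequal component variances**

The mixture likelihood is maximised by scoring a systematic grid of up to
200,000 parameter combinations and polishing the best candidates by
Newton-Raphson (EM fallback), with component SDs floored at 10⁻³ of the
sample SD to tame the likelihood's collapse degeneracy.

A gene is called bimodal only if **all four** criteria hold:

1. likelihood-ratio `2(ℓ₂ − ℓ₁)` has p < 0.001 against χ²₆ (six degrees of
   freedom rather than three, deliberately conservative);
2. misclassification area < 0.1 — the smaller mixture-weighted tail mass
   on the wrong side of the between-component density intersection;
3. at least 10% of samples on each side of that intersection (outlier
   guard);
4. expression is not associated with gender (two-sided OLS p ≥ 0.05).

Discovery then requires **replication**: the compound rule must pass in
each identifiable processing batch *and* in the pooled sample set before a
gene is confirmed. A parallel robust pathway re-runs the rule on 5%-trimmed
per-batch data, combines batch p-values by Fisher's method, and applies
Benjamini-Hochberg FDR control separately within the gender-associated and
non-gender-associated strata.

Confirmed genes feed two association layers: a cis-eQTL scan (±200 kb;
rank-inverse-normal expression regressed on additive genotype with age,
gender, heritage and a sibship random intercept; Cohen's κ agreement
between expression mode and the best dominant-model genotype grouping) and
a trait-versus-mode general linear model.

## Worked example

```python
import bimodalgene as bg

cfg = bg.SimulationConfig(n_genes=120, n_samples=225, group_sizes=(71, 47),
                          frac_bimodal=0.1, frac_batch_affected=0.05,
                          component_separation=6.0, mixing_range=(0.3, 0.7),
                          snp_concordance=1.0, seed=1)
expr, meta, geno, truth = bg.generate_dataset(cfg)

rows = bg.run_replication(expr, meta, bg.CriteriaConfig(mixture_budget=20_000))
table = bg.results_frame(rows)
print(table["confirmed"].sum())          # 11  (of 12 planted bimodal genes)

linked = [g for g, s in truth.driving_snp.items() if s]
hits = bg.eqtl_scan(expr, geno, meta, genes=linked)
print(min(h.p for h in hits))            # ~1e-64 (mode-determining cis-SNP)
```

On this seed the discovery confirms 11 of the 12 planted bimodal genes,
confirms none of the 6 planted batch-artifact genes (they light up only in
the pooled analysis, exactly the artifact the stratified design rejects),
and every SNP-driven gene is an overwhelming eQTL with mode-genotype
agreement κ = 1. The equivalent command-line workflow (generator defaults:
5% bimodal genes at separation 4):

```bash
bimodalgene simulate --out study --n-genes 120 --seed 1
bimodalgene replicate --expression study/expression.tsv \
    --metadata study/metadata.tsv --out results
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a synthetic study from the given seed and recomputes the full
pipeline: batch-stratified replication with Fisher/FDR evidence
combination, the cis-eQTL scan with κ agreement, and the trait-mode
association, printing a summary of what was recovered. The JSON written to
`--out` is the machine-readable result object; a human-readable run log is
placed alongside it.
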