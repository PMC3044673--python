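"""Genetic and phenotypic follow-up of bimodal genes.

Three layers: a cis-eQTL scan (rank-inverse-normal expression regressed on
additive genotype with age, gender and heritage covariates and a sibship
random intercept), Cohen's kappa agreement between expression mode and a
dominant-model genotype grouping, and trait-versus-mode association under
the same covariate structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .datasets import ExpressionDataset, GenotypeDataset, SampleMetadata
from .exceptions import DataError, DegenerateDataError

logger = logging.getLogger(__name__)

#: cis window: SNPs within this many bp of the gene span are tested.
CIS_WINDOW = 200_000

#: Blom offset for the rank-based inverse normal transform.
BLOM_C = 3.0 / 8.0


@dataclass
class EqtlResult:
    """Association of one gene-SNP pair."""

    gene_id: str
    snp_id: str
    effect: float
    p: float
    kappa: float
    n_used: int


def rank_inverse_normal(values) -> np.ndarray:
    """Map values to normal quantiles of their Blom-offset ranks.

    y_i = Phi^-1((r_i - 3/8) / (n + 1/4)) with average ranks for ties.
    Enforces a Gaussian marginal before linear modelling, so a strongly
    bimodal expression pattern cannot dominate the regression through its
    heavy mass points.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DataError(f"need >= 3 values, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant input")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - BLOM_C) / (x.size + 1.0 - 2.0 * BLOM_C))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / number of tests."""
    if n_tests < 1:
        raise DataError("n_tests must be >= 1")
    return alpha / n_tests


def cis_snp_select(gene_coords, geno: GenotypeDataset,
                   window: int = CIS_WINDOW) -> list[str]:
    """SNP ids within ``window`` bp of the gene span (inclusive bounds).

    ``gene_coords`` carries chrom, start, end with 1-based inclusive
    coordinates; a SNP at exactly start - window or end + window is
    included.
    """
    chrom = str(gene_coords["chrom"])
    lo = int(gene_coords["start"]) - window
    hi = int(gene_coords["end"]) + window
    snps = geno.snps
    mask = (snps["chrom"].astype(str) == chrom) & (snps["pos"] >= lo) & (snps["pos"] <= hi)
    return list(snps.index[mask])


def _mixed_or_ols_p(y, X, sibship):
    """Fit y ~ X with a sibship random intercept; OLS when all singletons.

    Returns (coefficient on the first non-constant column, two-sided p,
    n).  The mixed model is fitted by REML; its Wald z-test provides the
    p-value.  Singular designs raise and are handled by the caller.
    """
    groups = pd.Series(sibship).astype(str)
    all_singleton = groups.value_counts().max() == 1
    if all_singleton:
        res = sm.OLS(y, X).fit()
        return float(res.params[1]), float(res.pvalues[1]), int(len(y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups.to_numpy())
        res = model.fit(reml=True)
    beta = float(res.fe_params[1])
    se = float(res.bse_fe[1])
    if se <= 0 or not np.isfinite(se):
        raise np.linalg.LinAlgError("degenerate standard error")
    z = beta / se
    return beta, float(2.0 * stats.norm.sf(abs(z))), int(len(y))


def _covariate_matrix(meta: SampleMetadata, samples, extra_col=None):
    t = meta.table.loc[samples]
    gender = t["gender"]
    gender_ind = (gender == sorted(gender.unique())[-1]).astype(float)
    cols = {"age": t["age"].astype(float), "gender": gender_ind}
    if extra_col is not None and extra_col in t.columns:
        cols[extra_col] = t[extra_col].astype(float)
    return pd.DataFrame(cols, index=t.index)


def eqtl_scan(expr: ExpressionDataset, geno: GenotypeDataset,
              meta: SampleMetadata, genes=None, window: int = CIS_WINDOW,
              mode_labels: dict | None = None) -> list[EqtlResult]:
    """cis-eQTL scan for the requested genes.

    For each gene x cis-SNP pair, the rank-inverse-normal transformed
    expression is regressed on the additive genotype code with age,
    gender and heritage covariates and a sibship random intercept
    (REML; plain least squares when every sibship is a singleton).
    Missing genotypes are dropped pairwise.  When per-gene expression-mode
    labels are supplied, the maximum-kappa genotype-mode agreement is
    attached to each result.
    """
    if geno.genes is None:
        raise DataError("genotype dataset carries no gene coordinates")
    genes = list(genes) if genes is not None else list(expr.gene_ids)
    samples = [s for s in expr.sample_ids
               if s in geno.genotypes.columns and s in meta.table.index]
    if len(samples) < 30:
        raise DataError(f"need >= 30 overlapping samples, got {len(samples)}")

    results = []
    for gene_id in genes:
        if gene_id not in geno.genes.index:
            logger.warning("no coordinates for gene %r; skipped", gene_id)
            continue
        snp_ids = cis_snp_select(geno.genes.loc[gene_id], geno, window=window)
        if not snp_ids:
            continue
        y_all = rank_inverse_normal(expr.gene(gene_id, samples))
        labels = None
        if mode_labels is not None and gene_id in mode_labels:
            labels = np.asarray(pd.Series(mode_labels[gene_id]).loc[samples])
        covs = _covariate_matrix(meta, samples, extra_col="heritage")
        sib = meta.table.loc[samples, "sibship"].to_numpy()
        for snp_id in snp_ids:
            g = geno.snp(snp_id, samples)
            keep = ~np.isnan(g)
            if keep.sum() < 10 or np.ptp(g[keep]) == 0:
                continue
            X = np.column_stack([
                np.ones(keep.sum()), g[keep], covs.to_numpy()[keep]])
            try:
                beta, p, n_used = _mixed_or_ols_p(y_all[keep], X, sib[keep])
            except (np.linalg.LinAlgError, ValueError):
                logger.warning("singular design for %s x %s; skipped",
                               gene_id, snp_id)
                continue
            kappa = float("nan")
            if labels is not None:
                try:
                    kappa = kappa_agreement(labels[keep], g[keep])
                except DataError:
                    pass
            results.append(EqtlResult(gene_id=gene_id, snp_id=snp_id,
                                      effect=beta, p=p, kappa=kappa,
                                      n_used=n_used))
    return results


def kappa_agreement(mode_labels, genotypes) -> float:
    """Maximum Cohen's kappa over the four dominant-model pairings.

    The genotype is dichotomised under both dominant groupings
    ({0} vs {1,2} and {0,1} vs {2}); each grouping is paired with both
    orientations of the low/high mode labels, and the largest of the four
    kappas is returned.  kappa = 1 means the expression mode is fully
    predicted by carrier status.
    """
    labels = np.asarray(mode_labels)
    g = np.asarray(genotypes, dtype=float)
    keep = ~np.isnan(g)
    labels, g = labels[keep], g[keep]
    mode = (labels == "high").astype(int)
    if min(mode.sum(), (1 - mode).sum()) < 2:
        raise DataError("need >= 2 samples in each mode")
    best = -1.0
    for grouping in ((g > 0).astype(int), (g > 1).astype(int)):
        for oriented in (grouping, 1 - grouping):
            best = max(best, float(cohen_kappa_score(mode, oriented)))
    return best


def trait_mode_association(trait, mode_labels, meta: SampleMetadata,
                           samples=None):
    """Adjusted high-minus-low trait difference between expression modes.

    General linear model of the trait on the mode indicator with age and
    gender covariates and sibships as a random intercept (repeated
    measures).  Returns ``(difference, p)``; genes with fewer than 10
    non-missing trait values in either mode come back ``(nan, nan)``.
    """
    trait = pd.Series(trait)
    if samples is None:
        samples = list(trait.index)
    trait = trait.loc[samples].astype(float)
    labels = np.asarray(pd.Series(mode_labels, index=samples).loc[samples])
    keep = trait.notna().to_numpy()
    trait, labels = trait[keep], labels[keep]
    kept_samples = list(trait.index)
    mode = (labels == "high").astype(float)
    if min(int(mode.sum()), int((1 - mode).sum())) < 10:
        return float("nan"), float("nan")
    covs = _covariate_matrix(meta, kept_samples)
    X = np.column_stack([np.ones(len(kept_samples)), mode, covs.to_numpy()])
    sib = meta.table.loc[kept_samples, "sibship"].to_numpy()
    try:
        diff, p, _ = _mixed_or_ols_p(trait.to_numpy(), X, sib)
    except (np.linalg.LinAlgError, ValueError):
        return float("nan"), float("nan")
    return diff, p
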