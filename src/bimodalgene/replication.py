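"""Batch-group-stratified discovery with replication and FDR control.

Pooling expression values across processing batches can manufacture
bimodality out of nothing: an additive batch shift on a unimodal gene
splits the pooled distribution into two apparent modes.  The discovery
therefore runs the compound criteria separately within each identifiable
batch group and only *confirms* a gene that meets the criteria in every
group and in the full sample set.  A parallel robust pathway re-assesses
bimodality on 5%-trimmed per-group data, combines the two group p-values
by Fisher's method, and controls the false discovery rate separately in
the gender-associated and non-gender-associated strata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .criteria import BimodalityVerdict, CriteriaConfig, classify_gene
from .datasets import ExpressionDataset, SampleMetadata
from .exceptions import DataError

logger = logging.getLogger(__name__)

MIN_GROUP_SIZE = 10


def fisher_combine(pvalues):
    """Fisher's method: stat = -2 sum(ln p), chi-square with 2k df."""
    ps = np.asarray(pvalues, dtype=float)
    if ps.size < 2:
        raise DataError("need >= 2 p-values to combine")
    if np.any(ps > 1) or np.any(ps < 0):
        raise DataError("p-values must lie in [0, 1]")
    if np.any(ps == 0):
        logger.warning("p-value of 0 clamped to smallest positive float")
        ps = np.maximum(ps, np.nextafter(0.0, 1.0))
    stat = float(-2.0 * np.sum(np.log(ps)))
    return stat, float(stats.chi2.sf(stat, 2 * ps.size))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    ps = np.asarray(pvalues, dtype=float)
    if ps.size == 0:
        raise DataError("empty p-value vector")
    return multipletests(ps, method="fdr_bh")[1]


@dataclass
class GeneResultRow:
    """One gene's full discovery record (Table-3-style)."""

    gene_id: str
    verdicts: dict = field(default_factory=dict)          # group -> BimodalityVerdict (untrimmed)
    trimmed_verdicts: dict = field(default_factory=dict)  # group -> BimodalityVerdict (trimmed)
    fisher_stat: float = float("nan")
    fisher_p: float = float("nan")
    fdr_q: float = float("nan")
    gender_stratum: bool = False  # True = gender-associated stratum
    groups_met: frozenset = frozenset()
    confirmed: bool = False

    @property
    def gender_p(self) -> float:
        v = self.verdicts.get("All")
        return v.gender_p if v is not None else float("nan")


def stratified_fdr(rows: list[GeneResultRow],
                   gender_alpha: float = 0.05) -> list[GeneResultRow]:
    """Attach BH q-values computed separately within the gender strata.

    Genes are partitioned by gender association of expression (p < alpha
    versus p >= alpha) and the Fisher combined p-values receive a
    Benjamini-Hochberg correction within each stratum independently.
    """
    strata = {True: [], False: []}
    for row in rows:
        row.gender_stratum = bool(row.gender_p < gender_alpha)
        strata[row.gender_stratum].append(row)
    for is_gender, members in strata.items():
        if not members:
            logger.info("gender stratum %s empty; skipped", is_gender)
            continue
        ps = np.array([m.fisher_p for m in members])
        ok = np.isfinite(ps)
        if ok.any():
            qs = bh_fdr(ps[ok])
            for m, q in zip([m for m, o in zip(members, ok) if o], qs):
                m.fdr_q = float(q)
    return rows


def _trim_indices(values: np.ndarray, frac: float) -> np.ndarray:
    """Indices retained by 5%-trimming (mirrors transform.trim_extremes)."""
    k = int(math.floor(frac * values.size))
    if k == 0:
        return np.arange(values.size)
    order = np.argsort(values, kind="stable")
    return np.sort(order[k:-k])


def group_membership(flags: dict, named_groups) -> tuple:
    """Which analysis sets a gene met, and whether it counts as confirmed.

    ``flags`` maps analysis labels (batch groups plus "All") to the
    compound-rule outcome.  A gene is confirmed only when it meets the
    criteria in every identifiable batch group *and* in the full sample
    set, and at least two independent groups exist.
    """
    met = frozenset(label for label, ok in flags.items() if ok)
    confirmed = (len(named_groups) >= 2
                 and met == frozenset(named_groups) | {"All"})
    return met, confirmed


def run_replication(expr: ExpressionDataset, meta: SampleMetadata,
                    config: CriteriaConfig | None = None) -> list[GeneResultRow]:
    """Run the full batch-stratified discovery over all genes.

    Two pathways run side by side:

    * confirmation — the compound criteria on untrimmed data in each
      identifiable batch group and in the full sample set; a gene is
      confirmed when all pass;
    * robust replication — criteria on per-group 5%-trimmed data, group
      p-values combined by Fisher's method, BH-FDR within gender strata.

    Unassigned samples (batch group ``"unassigned"``) take part only in the
    all-samples analysis.  Groups smaller than 10 samples are excluded with
    a warning.
    """
    config = config or CriteriaConfig()
    groups = {}
    for g in meta.batch_groups():
        samples = [s for s in meta.samples_in_group(g) if s in expr.values.columns]
        if len(samples) < MIN_GROUP_SIZE:
            logger.warning("batch group %r has %d samples (< %d); excluded",
                           g, len(samples), MIN_GROUP_SIZE)
            continue
        groups[g] = samples
    if len(groups) < 1:
        raise DataError("no batch group with enough samples")
    all_samples = [s for s in meta.sample_ids if s in expr.values.columns]
    named = sorted(groups)

    rows = []
    for gene_id in expr.gene_ids:
        row = GeneResultRow(gene_id=gene_id)
        for label, samples in [*groups.items(), ("All", all_samples)]:
            vals = expr.gene(gene_id, samples)
            gender = meta.gender(samples)
            row.verdicts[label] = classify_gene(vals, gender, config,
                                                gene_id=gene_id)
        for label in named:
            samples = groups[label]
            vals = expr.gene(gene_id, samples)
            gender = meta.gender(samples)
            keep = _trim_indices(vals, config.trim_frac)
            row.trimmed_verdicts[label] = classify_gene(
                vals[keep], gender[keep], config, gene_id=gene_id)

        flags = {label: row.verdicts[label].final_call
                 for label in (*named, "All")}
        row.groups_met, row.confirmed = group_membership(flags, named)

        trimmed_ps = [row.trimmed_verdicts[g].p_bimodal for g in named]
        if len(trimmed_ps) >= 2:
            row.fisher_stat, row.fisher_p = fisher_combine(trimmed_ps)
        rows.append(row)

    stratified_fdr(rows, gender_alpha=config.gender_alpha)
    return rows


def compounding_counts(verdicts: list[BimodalityVerdict]) -> pd.Series:
    """Cumulative pass counts for the four criteria applied in order.

    Reproduces the non-increasing rows of the discovery summary: LRT p,
    + misclassification area, + 10% per component, + gender.
    """
    order = ["lrt", "misclass", "min_component", "gender"]
    counts = {}
    mask = np.ones(len(verdicts), dtype=bool)
    for i, crit in enumerate(order):
        flags = np.array([bool(v.passes.get(crit, False)) for v in verdicts])
        mask &= flags
        counts["+".join(order[: i + 1])] = int(mask.sum())
    return pd.Series(counts)


def results_frame(rows: list[GeneResultRow]) -> pd.DataFrame:
    """Flatten discovery rows into a tidy per-gene table."""
    records = []
    for row in rows:
        rec = {"gene_id": row.gene_id}
        for label, v in row.verdicts.items():
            rec[f"p_{label}"] = v.p_bimodal
            rec[f"call_{label}"] = v.final_call
        rec.update(
            gender_p=row.gender_p,
            fisher_stat=row.fisher_stat, fisher_p=row.fisher_p,
            fdr_q=row.fdr_q, gender_stratum=row.gender_stratum,
            groups_met=",".join(sorted(row.groups_met)),
            confirmed=row.confirmed,
        )
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("gene_id")


def set_concordance_p(set_a, set_b, universe: int) -> float:
    """One-sided Fisher's exact (hypergeometric) p for set overlap.

    Probability of an overlap at least as large as observed when two gene
    sets of the given sizes are drawn independently from a universe of
    ``universe`` genes.
    """
    a, b = set(set_a), set(set_b)
    if universe < len(a | b):
        raise DataError("universe smaller than the union of the sets")
    overlap = len(a & b)
    return float(stats.hypergeom.sf(overlap - 1, universe, len(a), len(b)))
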