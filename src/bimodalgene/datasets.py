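"""Light containers shared across the pipeline.

All tabular payloads are pandas objects; the wrappers only fix orientation
(genes x samples for expression, SNPs x samples for genotypes) and carry
the coordinate tables needed for cis-window logic.  Coordinates are held
1-based inclusive internally; BED input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError


@dataclass
class ExpressionDataset:
    """Genes x samples matrix of normalised log2 intensities."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataError(f"duplicate gene id: {dup!r}")

    @property
    def gene_ids(self):
        return list(self.values.index)

    @property
    def sample_ids(self):
        return list(self.values.columns)

    def gene(self, gene_id, samples=None) -> np.ndarray:
        if gene_id not in self.values.index:
            raise DataError(f"unknown gene id: {gene_id!r}")
        row = self.values.loc[gene_id]
        if samples is not None:
            row = row[samples]
        return row.to_numpy(dtype=float)


@dataclass
class SampleMetadata:
    """Per-sample annotations: batch group, gender, age, sibship, heritage,
    and any phenotypic trait columns."""

    table: pd.DataFrame  # index: sample ids

    UNASSIGNED = "unassigned"

    @property
    def sample_ids(self):
        return list(self.table.index)

    def batch_groups(self) -> list[str]:
        """Identifiable batch labels, excluding unassigned samples."""
        col = self.table["batch_group"].astype(str)
        return sorted(g for g in col.unique() if g != self.UNASSIGNED)

    def samples_in_group(self, group: str) -> list[str]:
        col = self.table["batch_group"].astype(str)
        return list(self.table.index[col == group])

    def gender(self, samples=None) -> np.ndarray:
        col = self.table["gender"]
        if samples is not None:
            col = col.loc[samples]
        return col.to_numpy()


@dataclass
class GenotypeDataset:
    """SNPs x samples matrix of 0/1/2 allele counts plus coordinates."""

    genotypes: pd.DataFrame  # index: snp ids, columns: sample ids; NaN = missing
    snps: pd.DataFrame       # index: snp ids; columns: chrom, pos (1-based)
    genes: pd.DataFrame = field(default=None)  # index: gene ids; chrom, start, end (1-based inclusive)

    def __post_init__(self):
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise DataError("genotype codes must be 0, 1, 2 or missing")
        if (self.snps["pos"] <= 0).any():
            raise DataError("SNP positions must be positive (1-based)")

    @property
    def snp_ids(self):
        return list(self.genotypes.index)

    def snp(self, snp_id, samples=None) -> np.ndarray:
        row = self.genotypes.loc[snp_id]
        if samples is not None:
            row = row[samples]
        return row.to_numpy(dtype=float)
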