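"""Readers and writers for the pipeline's file formats.

Tab-separated text is the canonical tabular dialect (period decimal
separator).  Genotypes are accepted either as a 0/1/2 matrix TSV or as a
VCF (GT field, diploid, unphased accepted; parsed with cyvcf2); gene spans
are read from BED (0-based half-open on disk, converted to 1-based
inclusive internally).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GenotypeDataset, SampleMetadata
from .exceptions import DataError


def _read_numeric_tsv(path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = index_name
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = df.index[bad][0]
            raise DataError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}")
        out[col] = converted
    return out


def read_expression(path) -> ExpressionDataset:
    """Read a genes x samples TSV (first column gene id, header sample ids)."""
    df = _read_numeric_tsv(path, "gene_id")
    return ExpressionDataset(values=df)  # duplicate ids rejected by the container


def write_expression(expr: ExpressionDataset, path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample_id"
    if df.index.duplicated().any():
        raise DataError("duplicate sample id in metadata")
    return SampleMetadata(table=df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t")


def read_genotypes_tsv(path, snp_coords_path=None) -> pd.DataFrame:
    """0/1/2 matrix TSV; missing cells stay NaN."""
    return _read_numeric_tsv(path, "snp_id")


def write_genotypes_tsv(geno: GenotypeDataset, matrix_path, coords_path) -> None:
    geno.genotypes.to_csv(matrix_path, sep="\t")
    geno.snps.to_csv(coords_path, sep="\t")


def read_snp_coords(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "snp_id"
    return df


def write_vcf(geno: GenotypeDataset, path) -> None:
    """Minimal VCF 4.2: CHROM, POS, ID, REF, ALT and unphased GT calls."""
    snps = geno.snps
    order = snps.sort_values(["chrom", "pos"]).index
    samples = list(geno.genotypes.columns)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp_id in order:
            row = snps.loc[snp_id]
            calls = [gt_map.get(v, "./.") if not np.isnan(v) else "./."
                     for v in geno.genotypes.loc[snp_id]]
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp_id}\tA\tG\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_vcf(path, gene_bed_path=None) -> GenotypeDataset:
    """Parse genotypes from a VCF into the 0/1/2 matrix representation."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snp_rows, geno_rows = [], []
    for i, var in enumerate(vcf):
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        snp_rows.append((snp_id, str(var.CHROM), int(var.POS)))
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=missing
        codes = np.asarray(var.gt_types, dtype=float)
        codes[codes == 3] = np.nan
        geno_rows.append(codes)
    vcf.close()
    if not snp_rows:
        raise DataError(f"no variants in {path}")
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"]).set_index("snp_id")
    genotypes = pd.DataFrame(np.vstack(geno_rows), index=snps.index, columns=samples)
    genes = read_gene_bed(gene_bed_path) if gene_bed_path else None
    return GenotypeDataset(genotypes=genotypes, snps=snps, genes=genes)


def read_gene_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> 1-based inclusive gene coordinate table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "bed_start", "bed_end", "gene_id"],
                     dtype={0: str})
    out = pd.DataFrame({
        "chrom": df["chrom"].astype(str).to_numpy(),
        "start": df["bed_start"].astype(int).to_numpy() + 1,
        "end": df["bed_end"].astype(int).to_numpy(),
    }, index=pd.Index(df["gene_id"], name="gene_id"))
    if (out["start"] > out["end"]).any():
        raise DataError("empty or inverted interval in BED input")
    return out


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    """1-based inclusive coordinates -> BED (0-based half-open)."""
    with open(path, "w") as fh:
        for gid, row in genes.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t{gid}\n")


def write_truth_json(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1, sort_keys=True)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
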