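"""Readers and writers for the pipeline's tab-separated interchange formats.

TSV is the native format throughout: the realistic inputs are Level-3-style
tables and diffability matters for testing.  Coordinates are 0-based
half-open internally (BED convention); VCF positions are 1-based and are
converted on the way in/out.  Every writer/reader pair round-trips:
``read(write(x)) == x``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coloc import SummaryStats
from .preprocess import CovariateSet
from .simulate import (
    READ_TABLE_COLUMNS,
    ExpressionSet,
    GeneModel,
    GenotypeMatrix,
    SpliceEffectTruth,
)

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_vcf_dosages",
    "read_vcf_dosages",
    "write_expression_set",
    "read_expression_set",
    "write_gene_model",
    "read_gene_model",
    "write_summary_stats",
    "read_summary_stats",
    "write_ld_matrix",
    "read_ld_matrix",
    "write_covariates",
    "read_covariates",
    "write_read_table",
    "read_read_table",
    "write_truth",
    "read_truth",
]


def _err(path: Path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


# -- genotypes ---------------------------------------------------------------

def write_genotypes(geno: GenotypeMatrix, dosage_path, meta_path) -> None:
    geno.dosages.rename_axis("sample_id").to_csv(dosage_path, sep="\t")
    geno.snps.to_csv(meta_path, sep="\t")


def read_genotypes(dosage_path, meta_path) -> GenotypeMatrix:
    dosages = pd.read_csv(dosage_path, sep="\t", index_col="sample_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="snp_id")
    return GenotypeMatrix(dosages, meta)


def write_vcf_dosages(geno: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with a DS (dosage) FORMAT field, uncompressed."""
    path = Path(path)
    samples = geno.sample_ids
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for snp_id, row in geno.snps.iterrows():
            ds = "\t".join(f"{d:g}" for d in geno.dosages[snp_id])
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t{snp_id}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tDS\t{ds}\n"
            )


def read_vcf_dosages(path) -> GenotypeMatrix:
    """Load a VCF with per-sample DS fields (via cyvcf2) into dosages.

    VCF POS is 1-based; internal positions are 0-based.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows, meta = [], [], []
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        ids.append(snp_id)
        rows.append(ds)
        maf_row = float(np.mean(ds) / 2.0)
        meta.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS - 1,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "maf": min(maf_row, 1.0 - maf_row),
                "info": 1.0,
            }
        )
    dosages = pd.DataFrame(
        np.column_stack(rows), index=pd.Index(samples, name="sample_id"), columns=ids
    )
    snps = pd.DataFrame(meta, index=pd.Index(ids, name="snp_id"))
    return GenotypeMatrix(dosages, snps)


# -- gene models -------------------------------------------------------------

def write_gene_model(gm: GeneModel, path) -> None:
    """Long-format TSV: exon rows carry BED-style coordinates, transcript rows
    a comma-joined exon list."""
    rows = []
    for eid, (s, e) in gm.exons.items():
        rows.append(
            dict(gene_id=gm.gene_id, chrom=gm.chrom, strand=gm.strand,
                 record="exon", id=eid, start=s, end=e, exon_ids="")
        )
    for tid, exon_ids in gm.transcripts.items():
        rows.append(
            dict(gene_id=gm.gene_id, chrom=gm.chrom, strand=gm.strand,
                 record="transcript", id=tid, start=-1, end=-1,
                 exon_ids=",".join(exon_ids))
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_model(path) -> list[GeneModel]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"exon_ids": str}, keep_default_na=False)
    models = []
    for gid, grp in df.groupby("gene_id", sort=False):
        exons: dict[str, tuple[int, int]] = {}
        transcripts: dict[str, tuple[str, ...]] = {}
        chrom = grp["chrom"].iloc[0]
        strand = grp["strand"].iloc[0]
        for i, row in grp.iterrows():
            if row["record"] == "exon":
                exons[row["id"]] = (int(row["start"]), int(row["end"]))
            elif row["record"] == "transcript":
                transcripts[row["id"]] = tuple(row["exon_ids"].split(","))
            else:
                raise _err(path, i + 2, f"unknown record type {row['record']!r}")
        models.append(GeneModel(gid, chrom, exons, transcripts, strand))
    return models


# -- expression --------------------------------------------------------------

def write_expression_set(expr: ExpressionSet, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr.exon_rpkm.rename_axis("sample_id").to_csv(out / "exon_rpkm.tsv", sep="\t")
    expr.junction_rpm.rename_axis("sample_id").to_csv(out / "junction_rpm.tsv", sep="\t")
    expr.transcript.rename_axis("sample_id").to_csv(out / "transcript.tsv", sep="\t")
    expr.gene.rename_axis("sample_id").to_frame().to_csv(out / "gene.tsv", sep="\t")
    write_gene_model(expr.gene_model, out / "gene_model.tsv")
    if expr.truth is not None:
        write_truth(expr.truth, out / "truth.json")


def read_expression_set(in_dir) -> ExpressionSet:
    d = Path(in_dir)
    gm = read_gene_model(d / "gene_model.tsv")[0]
    gene_df = pd.read_csv(d / "gene.tsv", sep="\t", index_col="sample_id")
    truth = read_truth(d / "truth.json") if (d / "truth.json").exists() else None
    return ExpressionSet(
        exon_rpkm=pd.read_csv(d / "exon_rpkm.tsv", sep="\t", index_col="sample_id"),
        junction_rpm=pd.read_csv(d / "junction_rpm.tsv", sep="\t", index_col="sample_id"),
        transcript=pd.read_csv(d / "transcript.tsv", sep="\t", index_col="sample_id"),
        gene=gene_df[gene_df.columns[0]],
        gene_model=gm,
        truth=truth,
    )


def write_truth(truth: SpliceEffectTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.__dict__, indent=1) + "\n")


def read_truth(path) -> SpliceEffectTruth:
    return SpliceEffectTruth(**json.loads(Path(path).read_text()))


# -- summary statistics ------------------------------------------------------

def write_summary_stats(stats: SummaryStats, stats_path, ld_path) -> None:
    df = stats.meta.copy()
    df.insert(len(df.columns), "z", stats.z)
    df.rename_axis("snp_id").to_csv(stats_path, sep="\t")
    write_ld_matrix(stats.sigma, stats.snp_ids, ld_path)


def read_summary_stats(stats_path, ld_path) -> SummaryStats:
    df = pd.read_csv(stats_path, sep="\t", index_col="snp_id")
    ids, sigma = read_ld_matrix(ld_path)
    if list(df.index) != ids:
        raise ValueError("summary-stat SNPs and LD matrix SNPs disagree")
    z = df.pop("z").to_numpy(dtype=float)
    return SummaryStats(ids, z, sigma, df)


def write_ld_matrix(sigma: np.ndarray, snp_ids, path) -> None:
    pd.DataFrame(sigma, index=pd.Index(snp_ids, name="snp_id"), columns=snp_ids).to_csv(
        path, sep="\t"
    )


def read_ld_matrix(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col="snp_id")
    return list(df.index), df.to_numpy(dtype=float)


# -- covariates, read tables -------------------------------------------------

def write_covariates(cov: CovariateSet, path) -> None:
    pd.concat([cov.pcs, cov.factors], axis=1).rename_axis("sample_id").to_csv(
        path, sep="\t"
    )


def read_covariates(path) -> CovariateSet:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    pc_cols = [c for c in df.columns if c.startswith("PC")]
    k_cols = [c for c in df.columns if c.startswith("K")]
    return CovariateSet(df[pc_cols], df[k_cols])


def write_read_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    missing = [c for c in READ_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: read table missing columns {missing}")
    return df[READ_TABLE_COLUMNS]
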