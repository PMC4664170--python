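"""Mapping-bias audit for splicing-QTL associations.

Aligners place reads carrying the reference allele more readily than reads
carrying the alternate allele.  If the tested feature contains a SNP in LD
with the index SNP, that differential read loss alone can fake a splicing
association.  The audit: find SNPs in LD (r^2 above a threshold, default 0.1)
whose position lies inside the associated feature, recount the feature using
only reads that do not overlap those SNPs, and re-test against the index
SNP's dosage adjusting for overall gene expression and genetic ancestry.  An
association that was significant before the recount but not after is flagged
``mapping_bias_suspect``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import AssociationRecord, _fit
from .preprocess import CovariateSet, rank_normalize

__all__ = [
    "BiasAuditConfig",
    "ld_table_from_dosages",
    "ld_snps_in_feature",
    "recount_excluding_reads",
    "retest_filtered",
    "audit_association",
]


@dataclass(frozen=True)
class BiasAuditConfig:
    """r^2 threshold and LD source for the audit."""

    r2_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in [0, 1]")


def ld_table_from_dosages(dosages: pd.DataFrame) -> pd.DataFrame:
    """Long-format LD table (snp_a, snp_b, r2) from a dosage matrix.

    Squared Pearson correlation of dosages; used when no external reference
    panel table is supplied.  Constant columns yield r2 = 0.
    """
    X = dosages.to_numpy(dtype=float)
    sd = X.std(axis=0)
    Xc = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Xc[:, sd == 0] = 0.0
    r = (Xc.T @ Xc) / len(dosages)
    ids = list(dosages.columns)
    ia, ib = np.triu_indices(len(ids), k=1)
    return pd.DataFrame(
        {
            "snp_a": [ids[i] for i in ia],
            "snp_b": [ids[j] for j in ib],
            "r2": r[ia, ib] ** 2,
        }
    )


def ld_snps_in_feature(
    index_snp: str,
    feature_intervals: Sequence[tuple[int, int]],
    ld_source: pd.DataFrame,
    snp_positions: Mapping[str, int],
    r2_threshold: float = 0.1,
) -> list[str]:
    """SNPs in LD with the index SNP that lie inside the feature.

    ``feature_intervals`` are 0-based half-open; pass one interval for an
    exon and the two flanking exonic segments for a junction (a junction read
    spans both).  ``ld_source`` is a long-format (snp_a, snp_b, r2) table and
    is treated as symmetric.  Strict inequality: r^2 must exceed the
    threshold.
    """
    hits = ld_source[
        (ld_source["snp_a"] == index_snp) | (ld_source["snp_b"] == index_snp)
    ]
    partners: dict[str, float] = {}
    for _, row in hits.iterrows():
        other = row["snp_b"] if row["snp_a"] == index_snp else row["snp_a"]
        partners[other] = max(partners.get(other, 0.0), float(row["r2"]))
    partners[index_snp] = 1.0  # the index SNP itself counts if it is exonic
    out = []
    for snp, r2 in partners.items():
        if r2 <= r2_threshold or snp not in snp_positions:
            continue
        pos = snp_positions[snp]
        if any(start <= pos < end for start, end in feature_intervals):
            out.append(snp)
    return sorted(out)


def recount_excluding_reads(
    read_table: pd.DataFrame, snps: Sequence[str]
) -> pd.DataFrame:
    """Per-sample feature counts using only reads that overlap none of ``snps``.

    Returns a samples x features count matrix.  With an empty SNP list the
    counts equal the full counts; adding SNPs can only reduce them.
    """
    snpset = set(snps)
    snp_col = read_table["snp_id"].fillna("")
    keep = ~snp_col.isin(snpset) if snpset else pd.Series(True, index=read_table.index)
    counts = (
        read_table.loc[keep]
        .groupby(["sample_id", "feature_id"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    # samples/features whose reads were all excluded must still appear (as 0)
    all_samples = pd.Index(sorted(read_table["sample_id"].unique()), name="sample_id")
    all_features = pd.Index(sorted(read_table["feature_id"].unique()), name="feature_id")
    counts = counts.reindex(index=all_samples, columns=all_features, fill_value=0)
    counts.columns.name = None
    return counts


def retest_filtered(
    g: np.ndarray,
    filtered_counts: np.ndarray,
    gene_abundance: np.ndarray,
    pcs: pd.DataFrame | None,
    snp_id: str = "snp",
    feature_id: str = "feature",
    gene_id: str = "gene",
    feature_kind: str = "exon",
) -> AssociationRecord:
    """Re-test a feature on bias-filtered counts.

    Covariates are overall gene expression and genetic ancestry (PCs) only —
    no hidden expression factors, since those were fit on the unfiltered
    data.  Constant filtered counts (all reads removed) are refused.
    """
    counts = np.asarray(filtered_counts, dtype=float)
    if np.std(counts) == 0:
        raise ValueError("filtered counts are constant; nothing left to test")
    y = rank_normalize(counts)
    expr = rank_normalize(np.asarray(gene_abundance, dtype=float))
    cov = None
    if pcs is not None and pcs.shape[1] > 0:
        cov = CovariateSet(pcs, pd.DataFrame(index=pcs.index))
    return _fit(y, g, expr, cov, snp_id, feature_id, feature_kind, gene_id)


def audit_association(
    record: AssociationRecord,
    retested: AssociationRecord,
    fdr_threshold: float = 0.05,
    nominal_alpha: float = 0.05,
) -> AssociationRecord:
    """Flag ``mapping_bias_suspect`` when significance is lost on re-test.

    Decision rule: the original record was a discovery (q < fdr_threshold)
    but the filtered re-test is not even nominally significant
    (p >= nominal_alpha).
    """
    was_hit = record.q is not None and record.q < fdr_threshold
    if was_hit and retested.p >= nominal_alpha:
        return replace(record, flags=set(record.flags) | {"mapping_bias_suspect"})
    return record
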