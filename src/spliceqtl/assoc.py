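"""Cis splicing-QTL association tests and the post-hoc reporting filters.

Three complementary linear models ask whether a risk SNP's dosage g shifts
isoform usage of a nearby gene beyond overall gene expression:

* exon:        rankINT(RPKM_exon_i) ~ g + rankINT(sum_{j!=i} RPKM_exon_j) + PCs + Ks
* junction:    rankINT(RPM_junction) ~ g + rankINT(gene abundance) + PCs + Ks
* transcript:  rankINT(transcript abundance) ~ g + rankINT(gene abundance) + PCs + Ks

The exon model adjusts for the gene's expression with the tested exon left
out, so short genes do not lose power to a covariate nearly collinear with
the response.  p-values come from the usual t reference distribution of the
OLS slope; the per-family Benjamini-Hochberg procedure controls FDR.
Transcript-level hits are then required to be corroborated by a nominally
significant, direction-consistent exon or junction signal, and genes with
known paralogs/pseudogenes are flagged rather than silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .preprocess import CovariateSet, rank_normalize
from .simulate import GeneModel

__all__ = [
    "AssociationRecord",
    "cis_features",
    "exon_association",
    "junction_association",
    "transcript_association",
    "bh_fdr",
    "assign_q",
    "corroborate_transcript_hits",
    "flag_paralogs",
    "records_to_frame",
]

FEATURE_KINDS = ("exon", "junction", "transcript")


@dataclass
class AssociationRecord:
    """One (SNP, feature) test: the risk-allele effect beta1 and its inference."""

    snp_id: str
    feature_id: str
    feature_kind: str
    gene_id: str
    beta1: float
    se: float
    p: float
    n_samples: int
    q: float | None = None
    flags: set[str] = field(default_factory=set)
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside (0, 1]")


def cis_features(
    snp_pos: int,
    gene_models: Iterable[GeneModel],
    window: int = 500_000,
    chrom: str | None = None,
) -> list[tuple[str, str, str]]:
    """Enumerate the testable features within +/- window of a SNP.

    Exons contribute only for genes with two or more exons, transcripts only
    for genes with two or more annotated transcripts; junctions always
    contribute.  A gene qualifies when its body comes within ``window`` bases
    of the SNP.  Returns (gene_id, feature_kind, feature_id) triples.
    """
    out: list[tuple[str, str, str]] = []
    for gm in gene_models:
        if chrom is not None and gm.chrom != chrom:
            continue
        dist = max(gm.start - snp_pos, snp_pos - gm.end, 0)
        if dist > window:
            continue
        if len(gm.exons) >= 2:
            out.extend((gm.gene_id, "exon", e) for e in gm.exon_ids)
        out.extend((gm.gene_id, "junction", j) for j in gm.junctions())
        if len(gm.transcripts) >= 2:
            out.extend((gm.gene_id, "transcript", t) for t in gm.transcripts)
    return out


def _fit(
    response: np.ndarray,
    g: np.ndarray,
    expr_covariate: np.ndarray | None,
    covariates: CovariateSet | None,
    snp_id: str,
    feature_id: str,
    feature_kind: str,
    gene_id: str,
) -> AssociationRecord:
    """OLS of a rank-normalized response on dosage plus nuisance covariates."""
    g = np.asarray(g, dtype=float)
    n = g.size
    if np.nanstd(g) == 0:
        raise ValueError(f"monomorphic SNP {snp_id}: constant dosage")
    if np.any(np.isnan(g)):
        g = np.where(np.isnan(g), np.nanmean(g), g)  # dosage semantics: mean-impute

    cols = [np.ones(n), g]
    names = ["const", "g"]
    if expr_covariate is not None:
        cols.append(np.asarray(expr_covariate, dtype=float))
        names.append("expr")
    if covariates is not None:
        block = covariates.design_block()
        if block.shape[0] != n:
            raise ValueError("covariate rows do not match the sample count")
        for j, name in enumerate(covariates.names):
            cols.append(block[:, j])
            names.append(name)
    X = np.column_stack(cols)
    if n <= X.shape[1]:
        raise ValueError(
            f"{n} samples cannot identify {X.shape[1]} coefficients"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        for j in range(1, X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad or names[1:]}")

    fit = sm.OLS(response, X).fit()
    return AssociationRecord(
        snp_id=snp_id,
        feature_id=feature_id,
        feature_kind=feature_kind,
        gene_id=gene_id,
        beta1=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(max(fit.pvalues[1], np.nextafter(0.0, 1.0))),
        n_samples=n,
        coefficients=dict(zip(names, map(float, fit.params))),
    )


def exon_association(
    g: np.ndarray,
    exon_matrix: pd.DataFrame,
    exon_id: str,
    covariates: CovariateSet | None,
    snp_id: str = "snp",
    gene_id: str = "gene",
) -> AssociationRecord:
    """Exon test with the leave-one-exon-out gene-expression adjustment.

    The response is the rank-normalized RPKM of the tested exon; the gene
    covariate is the raw RPKM summed over the *other* exons, rank-normalized.
    Requires a multi-exon gene.
    """
    if exon_matrix.shape[1] < 2:
        raise ValueError("exon test needs a gene with >= 2 exons")
    if exon_id not in exon_matrix.columns:
        raise ValueError(f"exon {exon_id} not in the matrix")
    y = rank_normalize(exon_matrix[exon_id].to_numpy(dtype=float))
    loo = exon_matrix.drop(columns=[exon_id]).sum(axis=1).to_numpy(dtype=float)
    return _fit(y, g, rank_normalize(loo), covariates, snp_id, exon_id, "exon", gene_id)


def junction_association(
    g: np.ndarray,
    junction_vector: np.ndarray,
    gene_abundance: np.ndarray,
    covariates: CovariateSet | None,
    snp_id: str = "snp",
    feature_id: str = "junction",
    gene_id: str = "gene",
) -> AssociationRecord:
    """Junction test: rank-normalized RPM adjusted for gene abundance."""
    y = rank_normalize(np.asarray(junction_vector, dtype=float))
    expr = rank_normalize(np.asarray(gene_abundance, dtype=float))
    return _fit(y, g, expr, covariates, snp_id, feature_id, "junction", gene_id)


def transcript_association(
    g: np.ndarray,
    transcript_vector: np.ndarray,
    gene_abundance: np.ndarray,
    covariates: CovariateSet | None,
    snp_id: str = "snp",
    feature_id: str = "transcript",
    gene_id: str = "gene",
) -> AssociationRecord:
    """Transcript test: rank-normalized abundance adjusted for gene abundance.

    Callers should have screened the transcript through ``filter_transcripts``
    (broad zero-expression makes the rank transform degenerate).
    """
    y = rank_normalize(np.asarray(transcript_vector, dtype=float))
    expr = rank_normalize(np.asarray(gene_abundance, dtype=float))
    return _fit(y, g, expr, covariates, snp_id, feature_id, "transcript", gene_id)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_q(
    records: Sequence[AssociationRecord], per_family: bool = True
) -> list[AssociationRecord]:
    """Attach BH q-values, by default within each test family separately
    (exon, junction, transcript), matching family-specific discovery counts;
    ``per_family=False`` pools all tests into one family."""
    records = list(records)
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        key = r.feature_kind if per_family else "all"
        groups.setdefault(key, []).append(i)
    out = list(records)
    for idx in groups.values():
        q = bh_fdr([records[i].p for i in idx])
        for i, qi in zip(idx, q):
            out[i] = replace(records[i], q=float(qi))
    return out


def _feature_sign_consistent(
    support: AssociationRecord, transcript: AssociationRecord, gm: GeneModel
) -> bool:
    """Direction consistency: a feature contained in the transcript must share
    beta1's sign; one excluded from it must have the opposite sign."""
    tid = transcript.feature_id
    if support.feature_kind == "exon":
        contained = support.feature_id in gm.transcripts[tid]
    else:
        contained = support.feature_id in gm.junctions_of_transcript(tid)
    same_sign = np.sign(support.beta1) == np.sign(transcript.beta1)
    return same_sign if contained else not same_sign


def corroborate_transcript_hits(
    records: Sequence[AssociationRecord],
    gene_models: Mapping[str, GeneModel],
    fdr_threshold: float = 0.05,
    nominal_alpha: float = 0.05,
) -> list[AssociationRecord]:
    """Flag transcript-level discoveries lacking exon/junction support.

    A transcript record with q < ``fdr_threshold`` gains the
    ``transcript_uncorroborated`` flag unless some exon or junction record of
    the same gene-SNP pair has p < ``nominal_alpha`` with a direction
    consistent with the transcript's exon composition.
    """
    out = []
    by_pair: dict[tuple[str, str], list[AssociationRecord]] = {}
    for r in records:
        by_pair.setdefault((r.snp_id, r.gene_id), []).append(r)
    for r in records:
        if r.feature_kind != "transcript" or r.q is None or r.q >= fdr_threshold:
            out.append(r)
            continue
        gm = gene_models[r.gene_id]
        supported = any(
            s.feature_kind in ("exon", "junction")
            and s.p < nominal_alpha
            and _feature_sign_consistent(s, r, gm)
            for s in by_pair[(r.snp_id, r.gene_id)]
        )
        if supported:
            out.append(r)
        else:
            out.append(replace(r, flags=set(r.flags) | {"transcript_uncorroborated"}))
    return out


def flag_paralogs(
    records: Sequence[AssociationRecord],
    paralog_table: Mapping[str, Sequence[str]],
) -> list[AssociationRecord]:
    """Flag records whose gene has a known paralog or pseudogene elsewhere.

    Exclusion is a reporting decision: records are flagged
    ``paralog_suspect``, never dropped.  Table entries for genes absent from
    the records produce a warning and are otherwise ignored.
    """
    known = {r.gene_id for r in records}
    for gid in paralog_table:
        if gid not in known:
            warnings.warn(f"paralog table names unknown gene {gid}", stacklevel=2)
    out = []
    for r in records:
        if r.gene_id in paralog_table and len(paralog_table[r.gene_id]) > 0:
            out.append(replace(r, flags=set(r.flags) | {"paralog_suspect"}))
        else:
            out.append(r)
    return out


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Flatten records for TSV output (flags as a semicolon-joined list)."""
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "feature_id": [r.feature_id for r in records],
            "feature_kind": [r.feature_kind for r in records],
            "gene_id": [r.gene_id for r in records],
            "beta1": [r.beta1 for r in records],
            "se": [r.se for r in records],
            "p": [r.p for r in records],
            "q": [r.q if r.q is not None else np.nan for r in records],
            "n_samples": [r.n_samples for r in records],
            "flags": [";".join(sorted(r.flags)) for r in records],
        }
    )
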