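"""Normalization and covariate construction for the cis association tests.

Responses are rank-based inverse-normal transformed; population structure is
summarized by principal components of standardized dosages (EIGENSTRAT
scaling) and global expression variability by truncated-SVD factors of
log2(RPKM + 0.25) exon values.  Defaults follow the 3-PC / 3-factor choice,
and the variance-explained vectors are exposed so a scree inspection can
justify or change them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .simulate import GenotypeMatrix

__all__ = [
    "CovariateSet",
    "rank_normalize",
    "counts_to_rpm",
    "genotype_pca",
    "hidden_expression_factors",
    "filter_transcripts",
    "build_covariates",
]


@dataclass
class CovariateSet:
    """Sample-aligned nuisance covariates: genotype PCs and expression factors.

    Both blocks are column-centered and share the row (sample) order of the
    data they were derived from.  ``pc_variance`` / ``factor_variance`` hold
    the fraction of variance each component explains, for scree inspection.
    """

    pcs: pd.DataFrame
    factors: pd.DataFrame
    pc_variance: np.ndarray = field(default_factory=lambda: np.array([]))
    factor_variance: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if len(self.pcs) and len(self.factors) and not self.pcs.index.equals(
            self.factors.index
        ):
            raise ValueError("PC and factor blocks have different sample orders")

    @property
    def sample_ids(self) -> list[str]:
        idx = self.pcs.index if len(self.pcs.columns) or len(self.pcs) else self.factors.index
        return list(idx)

    def design_block(self, samples: list[str] | None = None) -> np.ndarray:
        """Concatenated [PCs | factors] matrix for regression design."""
        pcs = self.pcs if samples is None else self.pcs.loc[samples]
        fac = self.factors if samples is None else self.factors.loc[samples]
        return np.column_stack([pcs.to_numpy(), fac.to_numpy()]) if (
            pcs.shape[1] or fac.shape[1]
        ) else np.empty((len(pcs), 0))

    @property
    def names(self) -> list[str]:
        return list(self.pcs.columns) + list(self.factors.columns)

    @classmethod
    def empty(cls, sample_ids: list[str]) -> "CovariateSet":
        idx = pd.Index(sample_ids, name="sample_id")
        return cls(pd.DataFrame(index=idx), pd.DataFrame(index=idx))


def rank_normalize(values) -> np.ndarray:
    """Rank-based inverse normal transform.

    Each value is replaced by its fractional rank mapped through the standard
    normal quantile function: Phi^{-1}((r - 0.5) / n), with average ranks for
    ties.  The half offset keeps the extremes finite and the output symmetric;
    a single value maps to 0.  Order-preserving and invariant under any
    strictly monotone transform of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot rank-normalize an empty vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    ranks = rankdata(x, method="average")
    return norm.ppf((ranks - 0.5) / x.size)


def counts_to_rpm(junction_counts, total_mapped_reads) -> np.ndarray:
    """Reads-per-million: count / (total mapped reads / 1e6), per sample."""
    counts = np.asarray(junction_counts, dtype=float)
    totals = np.asarray(total_mapped_reads, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("total mapped reads must be positive")
    return counts / (totals / 1e6)


def genotype_pca(genotypes: GenotypeMatrix, k: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k principal components of standardized dosages.

    Each SNP column is centered at its mean dosage and scaled by
    sqrt(p(1-p)) with p = mean/2 (the variance of a binomial allele count),
    the standardization EIGENSTRAT uses; monomorphic SNPs are dropped with a
    warning.  Returns the sample scores (left singular vectors scaled by the
    singular values) and the variance-explained fractions, eigenvalues in
    non-increasing order.
    """
    X = genotypes.dosages.to_numpy(dtype=float)
    p_hat = X.mean(axis=0) / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    if not poly.all():
        warnings.warn(
            f"dropping {np.count_nonzero(~poly)} monomorphic SNPs before PCA",
            stacklevel=2,
        )
    X = X[:, poly]
    p_hat = p_hat[poly]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic SNPs left for PCA")
    Xs = (X - 2.0 * p_hat) / np.sqrt(p_hat * (1.0 - p_hat))
    Xs = Xs - Xs.mean(axis=0)  # exact column centering after standardization
    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if k > rank:
        raise ValueError(f"requested {k} PCs but the standardized matrix has rank {rank}")
    scores = U[:, :k] * S[:k]
    pcs = pd.DataFrame(
        scores,
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    var = S**2 / np.sum(S**2)
    return pcs, var


def hidden_expression_factors(
    exon_rpkm: pd.DataFrame, m: int = 3, pseudocount: float = 0.25
) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-m hidden factors of global expression variability.

    Truncated SVD of the column-centered log2(RPKM + 0.25) exon matrix; the
    factor scores play the role PEER factors play as regression covariates,
    capturing the same leading variance components.  Returns scores and
    variance-explained fractions (non-increasing).
    """
    L = np.log2(exon_rpkm.to_numpy(dtype=float) + pseudocount)
    L = L - L.mean(axis=0)
    if np.allclose(L, 0.0):
        raise ValueError("expression matrix is constant; no factors to extract")
    U, S, _ = np.linalg.svd(L, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12))
    if m > rank:
        raise ValueError(f"requested {m} factors but the matrix has rank {rank}")
    scores = U[:, :m] * S[:m]
    factors = pd.DataFrame(
        scores,
        index=pd.Index(list(exon_rpkm.index), name="sample_id"),
        columns=[f"K{i + 1}" for i in range(m)],
    )
    var = S**2 / np.sum(S**2)
    return factors, var


def filter_transcripts(
    transcript_matrix: pd.DataFrame, max_zero_fraction: float = 0.25
) -> list[str]:
    """Transcripts expressed broadly enough to test.

    A transcript is kept iff the fraction of samples with zero expression is
    <= ``max_zero_fraction`` (zeros in strictly more than that fraction
    exclude it).  Gene-level eligibility (>= 2 annotated transcripts) is
    enforced where tests are enumerated, not here.
    """
    if transcript_matrix.size == 0:
        raise ValueError("empty transcript matrix")
    zero_frac = (transcript_matrix == 0).mean(axis=0)
    return list(transcript_matrix.columns[zero_frac <= max_zero_fraction])


def build_covariates(
    genotypes: GenotypeMatrix,
    exon_rpkm: pd.DataFrame,
    k: int = 3,
    m: int = 3,
    allow_fewer: bool = False,
) -> CovariateSet:
    """Convenience: genotype PCs + expression factors in one CovariateSet.

    With ``allow_fewer=True`` the requested k/m are capped at the achievable
    rank (with a warning) instead of raising — useful on small synthetic
    cohorts where a single gene's exon matrix cannot support 3 factors.
    """
    samples = genotypes.sample_ids
    if list(exon_rpkm.index) != samples:
        raise ValueError("genotype and expression sample orders differ")
    idx = pd.Index(samples, name="sample_id")

    def _capped(fn, requested, *args):
        if not allow_fewer:
            return fn(*args, requested)
        for trial in range(requested, 0, -1):
            try:
                out = fn(*args, trial)
            except ValueError:
                continue
            if trial < requested:
                warnings.warn(
                    f"capped {requested} components to {trial} (matrix rank)",
                    stacklevel=3,
                )
            return out
        raise ValueError("no usable components")

    if k > 0:
        pcs, pc_var = _capped(genotype_pca, k, genotypes)
    else:
        pcs, pc_var = pd.DataFrame(index=idx), np.array([])
    if m > 0:
        factors, f_var = _capped(hidden_expression_factors, m, exon_rpkm)
    else:
        factors, f_var = pd.DataFrame(index=idx), np.array([])
    return CovariateSet(pcs, factors, pc_var, f_var)
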