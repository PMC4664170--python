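"""Single-causal-variant fine-mapping posteriors and GWAS/sQTL overlap.

Under the assumption that exactly one SNP at a locus is causal, the vector of
marginal association z-scores is multivariate normal with mean ``z_i * r_ij``
(the causal SNP's z propagated through LD) and covariance equal to the LD
matrix Sigma.  The likelihood that SNP *i* is the causal one is therefore the
MVN density of the observed Z at that mean; normalizing the likelihoods gives
per-SNP causal posteriors P_i.  Credible sets are the minimal set of SNPs whose
posteriors cumulate past a threshold (default 0.95).

Two traits measured on the same SNP panel (a GWAS and a splicing QTL) are
compared by taking the credible set of one trait and summing the other trait's
posteriors over it: a cumulative probability below 0.05 excludes a shared
causal variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "SummaryStats",
    "PosteriorVector",
    "CredibleSet",
    "OverlapResult",
    "z_from_p_and_beta",
    "causal_log_likelihoods",
    "posteriors",
    "credible_set",
    "overlap",
    "merge_snp_universe",
    "finemap_snp_filter",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    """Per-locus summary association statistics with their LD matrix.

    Parameters
    ----------
    snp_ids : list of str
        SNP identifiers, one per element of ``z``.
    z : ndarray, shape (n,)
        Marginal association z-scores.
    sigma : ndarray, shape (n, n)
        LD correlation matrix (elements r_ij), unit diagonal.
    meta : DataFrame, optional
        Per-SNP metadata indexed by SNP id.  Recognized columns: ``pos``,
        ``maf``, ``info``, ``effect_allele``, ``other_allele``.
    """

    snp_ids: list[str]
    z: np.ndarray
    sigma: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.snp_ids)
        if self.z.shape != (n,):
            raise ValueError(f"z has shape {self.z.shape}, expected ({n},)")
        if self.sigma.shape != (n, n):
            raise ValueError(f"sigma has shape {self.sigma.shape}, expected ({n}, {n})")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z contains non-finite values")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("sigma is not symmetric")
        if not np.allclose(np.diag(self.sigma), 1.0, atol=1e-6):
            raise ValueError("sigma diagonal is not 1")
        if np.any(np.abs(self.sigma) > 1.0 + 1e-8):
            raise ValueError("sigma has |r| > 1")
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.snp_ids, name="snp_id"))

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, ids: Sequence[str]) -> "SummaryStats":
        """Restrict to ``ids`` (in the given order)."""
        idx = [self.snp_ids.index(s) for s in ids]
        return SummaryStats(
            snp_ids=list(ids),
            z=self.z[idx],
            sigma=self.sigma[np.ix_(idx, idx)],
            meta=self.meta.loc[list(ids)].copy(),
        )


@dataclass
class PosteriorVector:
    snp_ids: list[str]
    log_likelihoods: np.ndarray
    posteriors: np.ndarray

    def __post_init__(self) -> None:
        self.log_likelihoods = np.asarray(self.log_likelihoods, dtype=float)
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        if abs(self.posteriors.sum() - 1.0) > 1e-12:
            raise ValueError("posteriors do not sum to 1")
        if np.any(self.posteriors < 0):
            raise ValueError("negative posterior")

    def as_series(self) -> pd.Series:
        return pd.Series(self.posteriors, index=self.snp_ids, name="posterior")


@dataclass
class CredibleSet:
    """Minimal descending-posterior prefix with cumulative mass >= threshold."""

    snp_ids: list[str]
    cumulative_probability: float
    threshold: float = 0.95


@dataclass
class OverlapResult:
    set_trait: str
    credible_set: CredibleSet
    other_trait_cumulative: float
    decision: str  # "different_causal_variant" | "shared_not_excluded"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def z_from_p_and_beta(p: float, beta: float) -> float:
    """Signed z-score from a two-sided p-value and the effect's sign.

    z = sign(beta) * Phi^{-1}(1 - p/2).  ``p = 1`` maps to 0 regardless of beta.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if p == 1.0:
        return 0.0
    if beta == 0.0:
        raise ValueError("beta must be nonzero when p < 1 (its sign orients z)")
    return float(np.sign(beta) * norm.isf(p / 2.0))


def causal_log_likelihoods(
    stats: SummaryStats,
    ridge: float = 1e-6,
    include_normalizing_constant: bool = True,
) -> np.ndarray:
    """Log-likelihood that each SNP is the single causal variant.

    For SNP i the expected z-vector is ``M_i = z_i * sigma[:, i]`` and
    ``log l_i = log MVN(Z; M_i, sigma + ridge*I)``, evaluated via a Cholesky
    factorization shared across SNPs.  The additive MVN constant cancels in the
    posteriors; set ``include_normalizing_constant=False`` to drop it.
    """
    sigma = stats.sigma
    n = stats.n_snps
    cov = sigma + ridge * np.eye(n)
    try:
        chol = linalg.cho_factor(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            f"LD matrix not positive definite with ridge={ridge}; "
            "increase the ridge"
        ) from exc
    # residual matrix: column i is Z - z_i * sigma[:, i]
    resid = stats.z[:, None] - sigma * stats.z[None, :]
    solved = linalg.cho_solve(chol, resid)
    quad = np.einsum("ij,ij->j", resid, solved)
    logl = -0.5 * quad
    if include_normalizing_constant:
        logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
        logl -= 0.5 * (n * np.log(2.0 * np.pi) + logdet)
    return logl


def posteriors(
    log_likelihoods: np.ndarray,
    snp_ids: Sequence[str] | None = None,
) -> PosteriorVector:
    """Normalize per-SNP log-likelihoods to causal posteriors (log-sum-exp)."""
    logl = np.asarray(log_likelihoods, dtype=float)
    if logl.size == 0:
        raise ValueError("empty log-likelihood vector")
    if not np.all(np.isfinite(logl)):
        raise ValueError("non-finite log-likelihoods")
    p = np.exp(logl - logsumexp(logl))
    p = p / p.sum()  # clean residual rounding so the sum-to-1 invariant is exact
    if snp_ids is None:
        snp_ids = [f"snp_{i}" for i in range(logl.size)]
    return PosteriorVector(list(snp_ids), logl, p)


def credible_set(
    post: PosteriorVector,
    threshold: float = 0.95,
    positions: Sequence[float] | None = None,
) -> CredibleSet:
    """Minimal set of SNPs whose posteriors cumulate to >= ``threshold``.

    SNPs are ranked by descending posterior; ties break by genomic position
    then id so the set is deterministic.
    """
    n = len(post.snp_ids)
    if positions is None:
        positions = list(range(n))
    order = sorted(
        range(n), key=lambda i: (-post.posteriors[i], positions[i], post.snp_ids[i])
    )
    cum = 0.0
    chosen: list[str] = []
    for i in order:
        chosen.append(post.snp_ids[i])
        cum += float(post.posteriors[i])
        if cum >= threshold:
            break
    return CredibleSet(chosen, cum, threshold)


def overlap(
    set_from_trait_a: CredibleSet,
    posteriors_trait_b: PosteriorVector,
    set_trait: str = "trait_A",
    exclusion_threshold: float = 0.05,
) -> OverlapResult:
    """Cumulative posterior of trait B over trait A's credible set.

    A shared causal variant is excluded (decision ``different_causal_variant``)
    when that cumulative probability falls below ``exclusion_threshold``.
    """
    b_ids = set(posteriors_trait_b.snp_ids)
    missing = [s for s in set_from_trait_a.snp_ids if s not in b_ids]
    if missing:
        raise ValueError(f"credible-set SNPs absent from the other trait: {missing[:5]}")
    series = posteriors_trait_b.as_series()
    cum = float(series.loc[set_from_trait_a.snp_ids].sum())
    decision = (
        "different_causal_variant" if cum < exclusion_threshold else "shared_not_excluded"
    )
    return OverlapResult(set_trait, set_from_trait_a, cum, decision)


def merge_snp_universe(
    stats_a: SummaryStats, stats_b: SummaryStats
) -> tuple[SummaryStats, SummaryStats]:
    """Intersect two SNP panels and harmonize effect alleles.

    Keeps the intersection in ``stats_a``'s order.  When a SNP's effect/other
    alleles are swapped between the panels, the sign of trait B's z-score is
    flipped; allele pairs that match neither orientation are dropped with a
    warning.  Both LD matrices are subset consistently.
    """
    common = [s for s in stats_a.snp_ids if s in set(stats_b.snp_ids)]
    if not common:
        raise ValueError("no SNPs shared between the two panels")

    have_alleles = (
        "effect_allele" in stats_a.meta.columns
        and "effect_allele" in stats_b.meta.columns
    )
    keep: list[str] = []
    flip: list[str] = []
    if have_alleles:
        for s in common:
            ea_a = stats_a.meta.at[s, "effect_allele"]
            oa_a = stats_a.meta.at[s, "other_allele"]
            ea_b = stats_b.meta.at[s, "effect_allele"]
            oa_b = stats_b.meta.at[s, "other_allele"]
            if (ea_a, oa_a) == (ea_b, oa_b):
                keep.append(s)
            elif (ea_a, oa_a) == (oa_b, ea_b):
                keep.append(s)
                flip.append(s)
            else:
                warnings.warn(f"allele mismatch for {s}; dropped", stacklevel=2)
        if not keep:
            raise ValueError("no allele-consistent SNPs shared between the panels")
    else:
        keep = common

    sub_a = stats_a.subset(keep)
    sub_b = stats_b.subset(keep)
    if flip:
        flip_idx = [keep.index(s) for s in flip]
        sub_b.z[flip_idx] *= -1.0
        sub_b.meta.loc[flip, ["effect_allele", "other_allele"]] = sub_b.meta.loc[
            flip, ["other_allele", "effect_allele"]
        ].to_numpy()
    return sub_a, sub_b


def finemap_snp_filter(
    meta: pd.DataFrame, maf_min: float = 0.001, info_min: float = 0.5
) -> list[str]:
    """SNP ids passing the fine-mapping filters: MAF > maf_min and, for imputed
    SNPs (INFO present), INFO > info_min.  Genotyped SNPs with missing INFO pass."""
    maf = meta["maf"].astype(float)
    kept = maf > maf_min
    if "info" in meta.columns:
        info = pd.to_numeric(meta["info"], errors="coerce")
        kept &= info.isna() | (info > info_min)
    return list(meta.index[kept])
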