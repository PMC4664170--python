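"""Synthetic cohorts with known splicing ground truth.

Everything downstream of this module (normalization, cis association tests,
the mapping-bias audit, colocalization) is exercised on data produced here, so
the generators are first-class, deterministic code: identical (parameters,
seed) give bit-identical outputs.

What is emulated
----------------
* genotype dosages with block linkage disequilibrium, drawn by thresholding a
  Gaussian copula over haplotypes at the allele-frequency quantile;
* a two-isoform gene in which a causal SNP shifts the splicing proportion
  (psi) between the isoforms on the logit scale, observed as exon RPKM,
  junction RPM, and transcript abundances with log-normal noise and optional
  hidden confounders;
* GWAS z-score vectors distributed MVN(lambda * Sigma[:, c], Sigma) around a
  causal SNP c;
* read tables in which reads overlapping an exonic SNP are retained with an
  allele-dependent probability, the mechanism behind reference-mapping bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .coloc import SummaryStats

__all__ = [
    "LDBlockSpec",
    "GenotypeMatrix",
    "GeneModel",
    "SpliceEffectTruth",
    "ExpressionSet",
    "READ_TABLE_COLUMNS",
    "simulate_genotypes",
    "simulate_structured_genotypes",
    "simulate_expression",
    "simulate_summary_stats",
    "simulate_read_table",
    "two_isoform_gene",
]

READ_TABLE_COLUMNS = ["sample_id", "feature_id", "read_id", "snp_id", "allele"]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDBlockSpec:
    """Block-constant LD structure for a simulated locus.

    ``block_sizes`` partition the SNPs into blocks; within a block every SNP
    pair has latent correlation ``within_block_r`` (blocks are independent of
    each other).  ``mafs`` gives one alternate-allele frequency per SNP.
    Block-constant correlation with r < 1 is always positive semi-definite.
    """

    block_sizes: tuple[int, ...]
    within_block_r: float
    mafs: tuple[float, ...]

    def __init__(
        self,
        block_sizes: Sequence[int],
        within_block_r: float,
        mafs: Sequence[float] | float,
    ) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(b) for b in block_sizes))
        object.__setattr__(self, "within_block_r", float(within_block_r))
        n = sum(self.block_sizes)
        if np.isscalar(mafs):
            mafs = [float(mafs)] * n
        object.__setattr__(self, "mafs", tuple(float(m) for m in mafs))
        if any(b <= 0 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if len(self.mafs) != n:
            raise ValueError(
                f"{len(self.mafs)} MAFs given for {n} SNPs (sum of block sizes)"
            )
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError(
                f"within_block_r must be in [0, 1); block with r={self.within_block_r} "
                "implies a non-PSD or degenerate correlation matrix"
            )
        if any(not 0.0 < m <= 0.5 for m in self.mafs):
            raise ValueError("MAFs must lie in (0, 0.5]")

    @property
    def n_snps(self) -> int:
        return sum(self.block_sizes)

    def block_of(self, snp_index: int) -> int:
        edges = np.cumsum(self.block_sizes)
        return int(np.searchsorted(edges, snp_index, side="right"))

    def correlation(self) -> np.ndarray:
        """The implied SNP x SNP latent correlation matrix."""
        n = self.n_snps
        sigma = np.eye(n)
        start = 0
        for b in self.block_sizes:
            sigma[start : start + b, start : start + b] = self.within_block_r
            start += b
        np.fill_diagonal(sigma, 1.0)
        return sigma


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosages in [0, 2] plus per-SNP metadata.

    ``snps`` is indexed by snp_id with columns chrom, pos, ref, alt, maf, info.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.snps.index):
            raise ValueError("dosage columns and SNP metadata rows disagree")
        vals = self.dosages.to_numpy()
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages outside [0, 2]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.dosages[snp_id].to_numpy(dtype=float)

    def ld_r(self) -> pd.DataFrame:
        """Pairwise LD r (Pearson correlation of dosages)."""
        r = np.corrcoef(self.dosages.to_numpy(), rowvar=False)
        r = np.atleast_2d(r)
        return pd.DataFrame(r, index=self.snp_ids, columns=self.snp_ids)


@dataclass(frozen=True)
class GeneModel:
    """One gene: exon intervals, transcripts as exon lists, derived junctions.

    Coordinates are 0-based half-open.  A junction joins the end of one exon
    (donor) to the start of the next exon (acceptor) in a transcript's chain.
    """

    gene_id: str
    chrom: str
    exons: dict[str, tuple[int, int]]
    transcripts: dict[str, tuple[str, ...]]
    strand: str = "+"

    def __post_init__(self) -> None:
        for tid, exon_ids in self.transcripts.items():
            if len(exon_ids) == 0:
                raise ValueError(f"transcript {tid} has no exons")
            unknown = [e for e in exon_ids if e not in self.exons]
            if unknown:
                raise ValueError(f"transcript {tid} references unknown exons {unknown}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons.values())

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons.values())

    @property
    def exon_ids(self) -> list[str]:
        return list(self.exons)

    def junctions(self) -> dict[str, tuple[int, int]]:
        """junction_id -> (donor, acceptor); id is 'exonA|exonB'."""
        out: dict[str, tuple[int, int]] = {}
        for exon_ids in self.transcripts.values():
            ordered = sorted(exon_ids, key=lambda e: self.exons[e][0])
            for a, b in zip(ordered, ordered[1:]):
                out[f"{a}|{b}"] = (self.exons[a][1], self.exons[b][0])
        return dict(sorted(out.items(), key=lambda kv: kv[1]))

    def junctions_of_transcript(self, tid: str) -> list[str]:
        ordered = sorted(self.transcripts[tid], key=lambda e: self.exons[e][0])
        return [f"{a}|{b}" for a, b in zip(ordered, ordered[1:])]

    def exon_length(self, exon_id: str) -> int:
        s, e = self.exons[exon_id]
        return e - s

    def feature_interval(self, feature_kind: str, feature_id: str) -> tuple[int, int]:
        """Genomic interval of an exon, or the hull of a junction's flanks."""
        if feature_kind == "exon":
            return self.exons[feature_id]
        if feature_kind == "junction":
            a, b = feature_id.split("|")
            return (self.exons[a][0], self.exons[b][1])
        raise ValueError(f"no genomic interval for feature kind {feature_kind!r}")


@dataclass(frozen=True)
class SpliceEffectTruth:
    """Planted ground truth: which SNP shifts splicing, and by how much.

    psi (the affected transcript's share of the gene's output) follows
    ``logistic(baseline_logit_psi + effect_per_allele * dosage)``.
    """

    causal_snp_id: str
    gene_id: str
    affected_transcript_id: str
    baseline_logit_psi: float = 0.0
    effect_per_allele: float = 0.0

    def psi(self, dosage: np.ndarray) -> np.ndarray:
        x = self.baseline_logit_psi + self.effect_per_allele * np.asarray(dosage, float)
        return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ExpressionSet:
    """Expression tables for one gene, all samples x features.

    RPKM/RPM units follow a fixed convention: transcript abundances are in
    RPKM-like units, exon RPKM is the sum over transcripts containing the
    exon, junction RPM the sum over transcripts containing the junction, and
    the gene value is the sum over all transcripts.  Library size is fixed at
    ``library_size`` reads for count conversions.
    """

    exon_rpkm: pd.DataFrame
    junction_rpm: pd.DataFrame
    transcript: pd.DataFrame
    gene: pd.Series
    gene_model: GeneModel
    truth: SpliceEffectTruth | None = None
    confounders: pd.DataFrame | None = None
    library_size: float = 1e7

    @property
    def sample_ids(self) -> list[str]:
        return list(self.exon_rpkm.index)

    def expected_exon_counts(self, exon_id: str) -> np.ndarray:
        """Expected read count per sample for one exon (RPKM x kb x M-reads)."""
        length_kb = self.gene_model.exon_length(exon_id) / 1e3
        return self.exon_rpkm[exon_id].to_numpy() * length_kb * self.library_size / 1e6


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    spec: LDBlockSpec,
    n_samples: int,
    seed: int | np.random.Generator,
    chrom: str = "chr1",
    start_pos: int = 1_000_000,
    spacing: int = 1_000,
) -> GenotypeMatrix:
    """Draw dosage genotypes with block LD via a Gaussian-copula haplotype model.

    Each sample receives two haplotypes.  Per haplotype, a latent normal vector
    with the block correlation is thresholded at Phi^{-1}(maf): latent below
    the threshold carries the alternate allele.  Dosage = sum of haplotypes,
    so dosages are integers in {0, 1, 2} and the expected dosage is 2*maf.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    n = spec.n_snps
    r = spec.within_block_r
    mafs = np.asarray(spec.mafs)
    thresholds = norm.ppf(mafs)

    haplos = np.zeros((2, n_samples, n), dtype=np.int8)
    for h in range(2):
        latent = np.empty((n_samples, n))
        start = 0
        for b in spec.block_sizes:
            shared = rng.standard_normal((n_samples, 1))
            idio = rng.standard_normal((n_samples, b))
            latent[:, start : start + b] = np.sqrt(r) * shared + np.sqrt(1 - r) * idio
            start += b
        haplos[h] = latent < thresholds
    dosage = haplos.sum(axis=0).astype(float)

    snp_ids = [f"snp_{i:04d}" for i in range(n)]
    sample_idx = pd.Index([f"S{i:04d}" for i in range(n_samples)], name="sample_id")
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(n),
            "ref": "A",
            "alt": "G",
            "maf": mafs,
            "info": 1.0,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(
        pd.DataFrame(dosage, index=sample_idx, columns=snp_ids), snps
    )


def simulate_structured_genotypes(
    n_snps: int,
    n_per_pop: Sequence[int],
    maf_by_pop: Sequence[Sequence[float]] | None,
    seed: int | np.random.Generator,
    fst_like_spread: float = 0.15,
    chrom: str = "chr1",
    start_pos: int = 1_000_000,
    spacing: int = 1_000,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Independent SNPs with population-divergent allele frequencies.

    Used to plant ancestry structure: each population draws its per-SNP
    frequency around a shared ancestral frequency (spread controlled by
    ``fst_like_spread``) unless explicit ``maf_by_pop`` is given.  Returns the
    genotypes and the per-sample population labels (0, 1, ...).
    """
    rng = np.random.default_rng(seed)
    n_pops = len(n_per_pop)
    if maf_by_pop is None:
        ancestral = rng.uniform(0.1, 0.5, size=n_snps)
        freqs = np.clip(
            ancestral[None, :]
            + rng.normal(0.0, fst_like_spread, size=(n_pops, n_snps)),
            0.02,
            0.98,
        )
    else:
        freqs = np.asarray(maf_by_pop, dtype=float)
        if freqs.shape != (n_pops, n_snps):
            raise ValueError("maf_by_pop must be n_pops x n_snps")
    labels = np.repeat(np.arange(n_pops), n_per_pop)
    dosage = rng.binomial(2, freqs[labels, :]).astype(float)

    snp_ids = [f"snp_{i:04d}" for i in range(n_snps)]
    sample_ids = pd.Index([f"S{i:04d}" for i in range(len(labels))], name="sample_id")
    overall = dosage.mean(axis=0) / 2.0
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(n_snps),
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(overall, 1 - overall),
            "info": 1.0,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    geno = GenotypeMatrix(pd.DataFrame(dosage, index=sample_ids, columns=snp_ids), snps)
    return geno, labels


# ---------------------------------------------------------------------------
# Gene model + expression
# ---------------------------------------------------------------------------

def two_isoform_gene(
    gene_id: str = "GENE1",
    chrom: str = "chr1",
    start: int = 1_050_000,
    exon_length: int = 200,
    intron_length: int = 800,
    n_exons: int = 3,
) -> GeneModel:
    """Canonical exon-skipping gene: the long isoform uses all exons, the
    short isoform skips the middle one.  T_incl is the inclusion isoform."""
    if n_exons < 3:
        raise ValueError("exon skipping needs at least 3 exons")
    exons = {}
    pos = start
    for i in range(n_exons):
        exons[f"E{i + 1}"] = (pos, pos + exon_length)
        pos += exon_length + intron_length
    all_ids = tuple(exons)
    skip_ids = tuple(e for e in all_ids if e != "E2")
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        exons=exons,
        transcripts={"T_incl": all_ids, "T_skip": skip_ids},
    )


def simulate_expression(
    genotypes: GenotypeMatrix,
    gene_model: GeneModel,
    truth: SpliceEffectTruth,
    noise_sd: float = 0.2,
    n_confounders: int = 0,
    confounder_strength: float = 0.0,
    seed: int | np.random.Generator = 0,
    base_abundance: float = 50.0,
    library_size: float = 1e7,
) -> ExpressionSet:
    """Gene expression split between two isoforms according to psi(genotype).

    The gene total is ``base_abundance`` scaled by multiplicative confounders
    (each confounder is a standard-normal sample score with a N(0,
    confounder_strength) loading, applied on the log scale).  The affected
    transcript takes share psi, the remaining transcripts split 1 - psi
    equally, and each transcript gets independent log-normal noise
    exp(N(0, noise_sd)).  Exon RPKM / junction RPM / gene values are sums of
    transcript abundances over the containing transcripts, so at noise_sd=0
    the exon values equal those sums exactly.
    """
    if len(gene_model.transcripts) < 2 or len(gene_model.exons) < 2:
        raise ValueError("gene must have >= 2 transcripts and >= 2 exons")
    if truth.affected_transcript_id not in gene_model.transcripts:
        raise ValueError(f"unknown transcript {truth.affected_transcript_id}")
    if truth.causal_snp_id not in genotypes.snp_ids:
        raise ValueError(f"causal SNP {truth.causal_snp_id} not in genotypes")

    rng = np.random.default_rng(seed)
    samples = pd.Index(genotypes.sample_ids, name="sample_id")
    n = len(samples)
    g = genotypes.dosage(truth.causal_snp_id)
    psi = truth.psi(g)

    log_total = np.log(base_abundance) * np.ones(n)
    conf = None
    if n_confounders > 0:
        scores = rng.standard_normal((n, n_confounders))
        loadings = rng.normal(0.0, confounder_strength, size=n_confounders)
        log_total = log_total + scores @ loadings
        conf = pd.DataFrame(
            scores, index=samples, columns=[f"C{i + 1}" for i in range(n_confounders)]
        )
    total = np.exp(log_total)

    tids = list(gene_model.transcripts)
    others = [t for t in tids if t != truth.affected_transcript_id]
    shares = {truth.affected_transcript_id: psi}
    for t in others:
        shares[t] = (1.0 - psi) / len(others)
    abundance = {}
    for t in tids:
        noise = np.exp(rng.normal(0.0, noise_sd, size=n)) if noise_sd > 0 else 1.0
        abundance[t] = total * shares[t] * noise
    transcript = pd.DataFrame(abundance, index=samples)[tids]

    exon_rpkm = pd.DataFrame(
        {
            e: transcript[[t for t in tids if e in gene_model.transcripts[t]]].sum(axis=1)
            for e in gene_model.exon_ids
        },
        index=samples,
    )
    junction_rpm = pd.DataFrame(
        {
            j: transcript[
                [t for t in tids if j in gene_model.junctions_of_transcript(t)]
            ].sum(axis=1)
            for j in gene_model.junctions()
        },
        index=samples,
    )
    gene = transcript.sum(axis=1)
    gene.name = gene_model.gene_id

    return ExpressionSet(
        exon_rpkm=exon_rpkm,
        junction_rpm=junction_rpm,
        transcript=transcript,
        gene=gene,
        gene_model=gene_model,
        truth=truth,
        confounders=conf,
        library_size=library_size,
    )


def simulate_background_exons(
    confounders: pd.DataFrame | None,
    sample_ids: Sequence[str],
    n_features: int,
    confounder_strength: float,
    noise_sd: float,
    seed: int | np.random.Generator,
    base_rpkm: float = 20.0,
) -> pd.DataFrame:
    """Null exon RPKM matrix sharing the cohort's confounder scores.

    Emulates the rest of the transcriptome for the hidden-factor analysis:
    each background feature loads on the same per-sample confounder scores
    (loadings ~ N(0, confounder_strength) on the log scale) plus log-normal
    noise, with no genotype effect.  Factors fit on this matrix capture
    cohort-wide variability without absorbing the tested gene's own signal.
    """
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    log_x = np.log(base_rpkm) + rng.normal(0.0, noise_sd, size=(n, n_features))
    if confounders is not None and confounder_strength > 0:
        scores = confounders.to_numpy(dtype=float)
        loadings = rng.normal(0.0, confounder_strength, size=(scores.shape[1], n_features))
        log_x = log_x + scores @ loadings
    return pd.DataFrame(
        np.exp(log_x),
        index=pd.Index(list(sample_ids), name="sample_id"),
        columns=[f"bg_exon_{i:03d}" for i in range(n_features)],
    )


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_summary_stats(
    ld: np.ndarray,
    causal_index: int,
    lambda_ncp: float,
    seed: int | np.random.Generator,
    snp_ids: Sequence[str] | None = None,
    positions: Sequence[int] | None = None,
) -> SummaryStats:
    """One draw of marginal z-scores: Z ~ MVN(lambda * Sigma[:, c], Sigma).

    ``lambda_ncp`` is the causal SNP's expected z; LD propagates it to the
    rest of the locus.  Marginal variances are 1 by the unit diagonal.
    """
    sigma = np.asarray(ld, dtype=float)
    n = sigma.shape[0]
    if not (0 <= causal_index < n):
        raise ValueError(f"causal_index {causal_index} out of range for {n} SNPs")
    if not np.allclose(sigma, sigma.T, atol=1e-8):
        raise ValueError("LD matrix must be symmetric")
    rng = np.random.default_rng(seed)
    mean = lambda_ncp * sigma[:, causal_index]
    # eigen-decomposition tolerates the PSD-but-singular matrices block LD makes
    w, v = np.linalg.eigh(sigma)
    if w.min() < -1e-8:
        raise ValueError("LD matrix is not positive semi-definite")
    root = v @ (np.sqrt(np.clip(w, 0.0, None))[:, None] * v.T)
    z = mean + root @ rng.standard_normal(n)
    if snp_ids is None:
        snp_ids = [f"snp_{i:04d}" for i in range(n)]
    meta = pd.DataFrame(
        {"pos": positions if positions is not None else np.arange(n)},
        index=pd.Index(list(snp_ids), name="snp_id"),
    )
    return SummaryStats(list(snp_ids), z, sigma, meta)


# ---------------------------------------------------------------------------
# Read tables (mapping bias)
# ---------------------------------------------------------------------------

def simulate_read_table(
    genotypes: GenotypeMatrix,
    expression: ExpressionSet,
    exonic_snp_id: str,
    ref_mapping_rate: float = 1.0,
    alt_mapping_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    overlap_prob: float = 0.5,
    ld_with_causal: float | None = None,
    snp_pos: int | None = None,
) -> pd.DataFrame:
    """Per-read table for the gene's exons with allele-dependent read loss.

    Reads are drawn per sample per exon as Poisson around the expected count
    implied by the expression set.  In the exon containing the SNP, each read
    overlaps the SNP with probability ``overlap_prob``; an overlapping read
    carries the alternate allele with probability dosage/2 and is retained
    with probability ``alt_mapping_rate`` (``ref_mapping_rate`` for the
    reference allele).  Reads not overlapping the SNP are always retained,
    which is what the audit's read-exclusion recount exploits.

    The exonic SNP must be a column of ``genotypes``; as a convenience,
    ``ld_with_causal=1.0`` with an unknown id clones the causal SNP's dosages
    (the perfect-LD situation).  Returns a DataFrame with columns
    sample_id, feature_id, read_id, snp_id, allele (snp_id/allele empty for
    non-overlapping reads).
    """
    if not (0.0 < ref_mapping_rate <= 1.0 and 0.0 < alt_mapping_rate <= 1.0):
        raise ValueError("mapping rates must lie in (0, 1]")
    if not 0.0 <= overlap_prob <= 1.0:
        raise ValueError("overlap_prob must lie in [0, 1]")
    gm = expression.gene_model
    if exonic_snp_id in genotypes.snp_ids:
        snp_dosage = genotypes.dosage(exonic_snp_id)
        if snp_pos is None:
            snp_pos = int(genotypes.snps.at[exonic_snp_id, "pos"])
    elif ld_with_causal == 1.0 and expression.truth is not None:
        snp_dosage = genotypes.dosage(expression.truth.causal_snp_id)
    else:
        raise ValueError(
            f"{exonic_snp_id} not in the genotype matrix; only ld_with_causal=1.0 "
            "(cloning the causal SNP) is supported for absent SNPs"
        )
    host_exon = None
    if snp_pos is not None:
        for e, (s, t) in gm.exons.items():
            if s <= snp_pos < t:
                host_exon = e
                break
    if host_exon is None:
        # position not supplied or not exonic: place the SNP in the first exon
        host_exon = gm.exon_ids[0]

    rng = np.random.default_rng(seed)
    samples = expression.sample_ids
    rows: list[pd.DataFrame] = []
    for e in gm.exon_ids:
        lam = np.maximum(expression.expected_exon_counts(e), 0.0)
        n_reads = rng.poisson(lam)
        if e != host_exon:
            counts = n_reads
            n_over = np.zeros_like(counts)
            n_alt_kept = np.zeros_like(counts)
            n_ref_kept = np.zeros_like(counts)
            n_plain = counts
        else:
            n_over = rng.binomial(n_reads, overlap_prob)
            n_plain = n_reads - n_over
            p_alt = np.clip(snp_dosage / 2.0, 0.0, 1.0)
            n_alt = rng.binomial(n_over, p_alt)
            n_ref = n_over - n_alt
            n_alt_kept = rng.binomial(n_alt, alt_mapping_rate)
            n_ref_kept = rng.binomial(n_ref, ref_mapping_rate)
        ref_allele = genotypes.snps.at[exonic_snp_id, "ref"] if exonic_snp_id in genotypes.snp_ids else "A"
        alt_allele = genotypes.snps.at[exonic_snp_id, "alt"] if exonic_snp_id in genotypes.snp_ids else "G"
        per_sample = n_plain + n_ref_kept + n_alt_kept
        sample_col = np.repeat(samples, per_sample)
        snp_col = np.concatenate(
            [
                np.repeat(
                    ["", exonic_snp_id, exonic_snp_id],
                    [n_plain[i], n_ref_kept[i], n_alt_kept[i]],
                )
                for i in range(len(samples))
            ]
        ) if len(samples) else np.array([], dtype=object)
        allele_col = np.concatenate(
            [
                np.repeat(
                    ["", ref_allele, alt_allele],
                    [n_plain[i], n_ref_kept[i], n_alt_kept[i]],
                )
                for i in range(len(samples))
            ]
        ) if len(samples) else np.array([], dtype=object)
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample_col,
                    "feature_id": e,
                    "read_id": "",
                    "snp_id": snp_col,
                    "allele": allele_col,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table["read_id"] = [f"r{i:07d}" for i in range(len(table))]
    return table[READ_TABLE_COLUMNS]
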