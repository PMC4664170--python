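"""End-to-end orchestration: simulate -> preprocess -> associate -> audit -> coloc.

``run_pipeline`` drives a full synthetic locus through every stage with known
ground truth: genotypes with block LD, a two-isoform gene whose splicing a
chosen SNP shifts, the three cis association tests with FDR control and the
corroboration/paralog filters, the mapping-bias audit on a simulated read
table, and finally the single-causal-variant overlap decision between the
splicing-QTL signal and a simulated GWAS signal.  All thresholds live in
``PipelineConfig`` and every output, including the run log, is deterministic
given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import (
    assign_q,
    cis_features,
    corroborate_transcript_hits,
    exon_association,
    flag_paralogs,
    junction_association,
    records_to_frame,
    transcript_association,
)
from .bias import (
    audit_association,
    ld_snps_in_feature,
    ld_table_from_dosages,
    recount_excluding_reads,
    retest_filtered,
)
from .coloc import (
    causal_log_likelihoods,
    credible_set,
    overlap,
    posteriors,
    z_from_p_and_beta,
)
from .coloc import SummaryStats
from .io import (
    write_covariates,
    write_expression_set,
    write_genotypes,
    write_read_table,
    write_summary_stats,
)
from .preprocess import build_covariates, filter_transcripts
from .simulate import (
    LDBlockSpec,
    SpliceEffectTruth,
    simulate_background_exons,
    simulate_expression,
    simulate_genotypes,
    simulate_read_table,
    simulate_summary_stats,
    two_isoform_gene,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every knob of the synthetic end-to-end run, with the analysis defaults:
    +/-500 kb cis window, FDR 0.05, 3 PCs, 3 factors, bias r^2 0.1, 0.95
    credible sets with the 0.05 exclusion rule."""

    seed: int = 0
    n_samples: int = 300
    block_sizes: tuple[int, ...] = (10, 10, 10)
    within_block_r: float = 0.8
    maf: float = 0.3
    causal_snp_index: int = 5
    effect_per_allele: float = 0.6
    baseline_logit_psi: float = 0.0
    noise_sd: float = 0.2
    n_confounders: int = 2
    confounder_strength: float = 0.3
    # GWAS signal: shared causal SNP, or an index in another LD block
    gwas_causal_index: int | None = None
    gwas_lambda: float = 6.0
    # mapping-bias audit inputs
    exonic_snp_index: int | None = None
    ref_mapping_rate: float = 1.0
    alt_mapping_rate: float = 1.0
    # analysis thresholds
    cis_window: int = 500_000
    fdr_threshold: float = 0.05
    n_pcs: int = 3
    n_factors: int = 3
    bias_r2: float = 0.1
    credible_threshold: float = 0.95
    exclusion_threshold: float = 0.05
    ridge: float = 1e-6
    paralog_table: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, lo, hi, v in [
            ("fdr_threshold", 0, 1, self.fdr_threshold),
            ("bias_r2", 0, 1, self.bias_r2),
            ("credible_threshold", 0, 1, self.credible_threshold),
            ("exclusion_threshold", 0, 1, self.exclusion_threshold),
        ]:
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


def _sqtl_summary_stats(genotypes, feature_values, gene_abundance, covariates, kind):
    """Per-SNP splicing z-scores for the top feature, LD from the dosages."""
    test = junction_association if kind == "junction" else transcript_association
    zs = []
    for snp in genotypes.snp_ids:
        g = genotypes.dosage(snp)
        if np.std(g) == 0:
            zs.append(0.0)
            continue
        rec = test(g, feature_values, gene_abundance, covariates, snp_id=snp)
        zs.append(z_from_p_and_beta(rec.p, rec.beta1) if rec.p < 1 else 0.0)
    sigma = genotypes.ld_r().to_numpy()
    meta = genotypes.snps[["pos", "maf", "info"]].copy()
    return SummaryStats(genotypes.snp_ids, np.asarray(zs), sigma, meta)


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run every stage on one synthetic locus; return the report bundle.

    The report carries the association table (with flags), the bias-audit
    before/after record, the two posterior vectors, the GWAS credible set and
    the overlap decision.  When ``out_dir`` is given, all tables and a JSON
    report (plus a run log listing the version, seed, and every threshold)
    are written there.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    # -- stage 1: synthesis --------------------------------------------------
    spec = LDBlockSpec(cfg.block_sizes, cfg.within_block_r, cfg.maf)
    geno = simulate_genotypes(spec, cfg.n_samples, int(seeds[0]))
    gene = two_isoform_gene(start=int(geno.snps["pos"].max()) + 10_000)
    causal_id = geno.snp_ids[cfg.causal_snp_index]
    truth = SpliceEffectTruth(
        causal_snp_id=causal_id,
        gene_id=gene.gene_id,
        affected_transcript_id="T_incl",
        baseline_logit_psi=cfg.baseline_logit_psi,
        effect_per_allele=cfg.effect_per_allele,
    )
    expr = simulate_expression(
        geno, gene, truth,
        noise_sd=cfg.noise_sd,
        n_confounders=cfg.n_confounders,
        confounder_strength=cfg.confounder_strength,
        seed=int(seeds[1]),
    )

    # -- stage 2: covariates -------------------------------------------------
    # hidden factors come from a cohort-wide background expression matrix, not
    # the tested gene's own exons (which would absorb the splicing signal)
    background = simulate_background_exons(
        expr.confounders, geno.sample_ids, 40,
        cfg.confounder_strength, cfg.noise_sd, int(seeds[4]),
    )
    covariates = build_covariates(
        geno, background, k=cfg.n_pcs, m=cfg.n_factors, allow_fewer=True
    )

    # -- stage 3: cis association tests for the index SNP --------------------
    snp_pos = int(geno.snps.at[causal_id, "pos"])
    g = geno.dosage(causal_id)
    kept_transcripts = set(filter_transcripts(expr.transcript))
    records = []
    for gene_id, kind, fid in cis_features(snp_pos, [gene], cfg.cis_window, gene.chrom):
        if kind == "exon":
            rec = exon_association(g, expr.exon_rpkm, fid, covariates, causal_id, gene_id)
        elif kind == "junction":
            rec = junction_association(
                g, expr.junction_rpm[fid].to_numpy(), expr.gene.to_numpy(),
                covariates, causal_id, fid, gene_id,
            )
        else:
            if fid not in kept_transcripts:
                continue
            rec = transcript_association(
                g, expr.transcript[fid].to_numpy(), expr.gene.to_numpy(),
                covariates, causal_id, fid, gene_id,
            )
        records.append(rec)
    records = assign_q(records, per_family=True)
    records = corroborate_transcript_hits(
        records, {gene.gene_id: gene}, cfg.fdr_threshold
    )
    records = flag_paralogs(records, cfg.paralog_table)

    # -- stage 4: mapping-bias audit on the top exon hit ---------------------
    exon_hits = [r for r in records if r.feature_kind == "exon"]
    top_exon = min(exon_hits, key=lambda r: r.p)
    exonic_snp = (
        geno.snp_ids[cfg.exonic_snp_index]
        if cfg.exonic_snp_index is not None
        else causal_id
    )
    exon_interval = gene.exons[top_exon.feature_id]
    snp_pos_in_exon = exon_interval[0] + 10
    reads = simulate_read_table(
        geno, expr, exonic_snp,
        ref_mapping_rate=cfg.ref_mapping_rate,
        alt_mapping_rate=cfg.alt_mapping_rate,
        seed=int(seeds[2]),
        snp_pos=snp_pos_in_exon,
    )
    ld_table = ld_table_from_dosages(geno.dosages)
    positions = {exonic_snp: snp_pos_in_exon}
    suspects = ld_snps_in_feature(
        causal_id, [exon_interval], ld_table, positions, cfg.bias_r2
    )
    audit = None
    if suspects:
        filtered = recount_excluding_reads(reads, suspects)
        filtered = filtered.reindex(index=expr.sample_ids, fill_value=0)
        retested = retest_filtered(
            g, filtered[top_exon.feature_id].to_numpy(), expr.gene.to_numpy(),
            covariates.pcs, causal_id, top_exon.feature_id, gene.gene_id,
        )
        audited = audit_association(top_exon, retested, cfg.fdr_threshold)
        records = [audited if r is top_exon else r for r in records]
        audit = {
            "feature_id": top_exon.feature_id,
            "excluded_snps": suspects,
            "p_before": top_exon.p,
            "p_after": retested.p,
            "mapping_bias_suspect": "mapping_bias_suspect" in audited.flags,
        }

    # -- stage 5: colocalization ---------------------------------------------
    top = min(records, key=lambda r: r.p)
    feature_values = (
        expr.junction_rpm[top.feature_id].to_numpy()
        if top.feature_kind == "junction"
        else expr.transcript[top.feature_id].to_numpy()
        if top.feature_kind == "transcript"
        else expr.exon_rpkm[top.feature_id].to_numpy()
    )
    if top.feature_kind == "exon":
        loo = expr.exon_rpkm.drop(columns=[top.feature_id]).sum(axis=1).to_numpy()
        sqtl_stats = _sqtl_summary_stats(geno, feature_values, loo, covariates, "junction")
    else:
        sqtl_stats = _sqtl_summary_stats(
            geno, feature_values, expr.gene.to_numpy(), covariates, top.feature_kind
        )
    gwas_causal = (
        cfg.gwas_causal_index if cfg.gwas_causal_index is not None else cfg.causal_snp_index
    )
    sigma = sqtl_stats.sigma
    gwas_stats = simulate_summary_stats(
        sigma, gwas_causal, cfg.gwas_lambda, int(seeds[3]),
        snp_ids=geno.snp_ids, positions=geno.snps["pos"].to_numpy(),
    )
    post_gwas = posteriors(
        causal_log_likelihoods(gwas_stats, cfg.ridge), gwas_stats.snp_ids
    )
    post_sqtl = posteriors(
        causal_log_likelihoods(sqtl_stats, cfg.ridge), sqtl_stats.snp_ids
    )
    pos_arr = geno.snps["pos"].to_numpy()
    cset = credible_set(post_gwas, cfg.credible_threshold, pos_arr)
    result = overlap(cset, post_sqtl, "gwas", cfg.exclusion_threshold)

    report = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "cis_window": cfg.cis_window,
            "fdr": cfg.fdr_threshold,
            "n_pcs": cfg.n_pcs,
            "n_factors": cfg.n_factors,
            "bias_r2": cfg.bias_r2,
            "credible": cfg.credible_threshold,
            "exclusion": cfg.exclusion_threshold,
            "ridge": cfg.ridge,
        },
        "truth": {
            "causal_snp": causal_id,
            "gwas_causal_snp": geno.snp_ids[gwas_causal],
            "effect_per_allele": cfg.effect_per_allele,
        },
        "associations": records_to_frame(records),
        "audit": audit,
        "gwas_credible_set": {
            "snp_ids": cset.snp_ids,
            "cumulative_probability": cset.cumulative_probability,
        },
        "overlap": {
            "set_trait": result.set_trait,
            "other_trait_cumulative": result.other_trait_cumulative,
            "decision": result.decision,
        },
        "posteriors": pd.DataFrame(
            {
                "snp_id": geno.snp_ids,
                "pos": pos_arr,
                "gwas_posterior": post_gwas.posteriors,
                "sqtl_posterior": post_sqtl.posteriors,
            }
        ),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotypes(geno, out / "dosages.tsv", out / "snps.tsv")
        write_expression_set(expr, out / "expression")
        write_covariates(covariates, out / "covariates.tsv")
        report["associations"].to_csv(out / "associations.tsv", sep="\t", index=False)
        write_read_table(reads, out / "reads.tsv")
        write_summary_stats(gwas_stats, out / "gwas_stats.tsv", out / "ld.tsv")
        report["posteriors"].to_csv(out / "posteriors.tsv", sep="\t", index=False)
        serializable = {
            k: v for k, v in report.items() if k not in ("associations", "posteriors")
        }
        (out / "report.json").write_text(json.dumps(serializable, indent=1) + "\n")
        log_lines = [f"spliceqtl {__version__}", f"seed {cfg.seed}"] + [
            f"{k} {v}" for k, v in report["thresholds"].items()
        ]
        for r in records:
            if r.flags:
                log_lines.append(
                    f"flagged {r.snp_id} {r.feature_kind} {r.feature_id}: "
                    + ";".join(sorted(r.flags))
                )
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
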