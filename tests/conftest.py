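import numpy as np
import pytest

from spliceqtl import (
    GenotypeMatrix,
    LDBlockSpec,
    SpliceEffectTruth,
    simulate_expression,
    simulate_genotypes,
    two_isoform_gene,
)


@pytest.fixture(scope="session")
def small_cohort():
    """200 samples, two 5-SNP LD blocks, a planted exon-skipping effect."""
    spec = LDBlockSpec([5, 5], 0.8, 0.3)
    geno = simulate_genotypes(spec, 200, seed=11)
    gene = two_isoform_gene(start=int(geno.snps["pos"].max()) + 10_000)
    truth = SpliceEffectTruth(
        causal_snp_id="snp_0002",
        gene_id=gene.gene_id,
        affected_transcript_id="T_incl",
        baseline_logit_psi=0.0,
        effect_per_allele=0.8,
    )
    expr = simulate_expression(geno, gene, truth, noise_sd=0.2, seed=12)
    return geno, gene, truth, expr


@pytest.fixture(scope="session")
def null_cohort():
    """Same shape but no splicing effect and no noise (deterministic psi)."""
    spec = LDBlockSpec([4], 0.5, 0.25)
    geno = simulate_genotypes(spec, 120, seed=21)
    gene = two_isoform_gene(start=int(geno.snps["pos"].max()) + 10_000)
    truth = SpliceEffectTruth(
        causal_snp_id="snp_0001",
        gene_id=gene.gene_id,
        affected_transcript_id="T_incl",
    )
    expr = simulate_expression(geno, gene, truth, noise_sd=0.0, seed=22)
    return geno, gene, truth, expr
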