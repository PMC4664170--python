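"""Cis association tests: estimation, inference, FDR, and reporting filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spliceqtl import (
    AssociationRecord,
    LDBlockSpec,
    SpliceEffectTruth,
    assign_q,
    bh_fdr,
    cis_features,
    corroborate_transcript_hits,
    exon_association,
    flag_paralogs,
    junction_association,
    rank_normalize,
    simulate_expression,
    simulate_genotypes,
    transcript_association,
    two_isoform_gene,
)
from spliceqtl.simulate import GeneModel


def _record(kind, fid, beta1, p, q=None, snp="rs1", gene="G"):
    return AssociationRecord(snp, fid, kind, gene, beta1, 0.1, p, 100, q=q)


class TestCisFeatures:
    def _gene(self, start):
        return two_isoform_gene(gene_id="G", start=start)

    def test_gene_starting_just_inside_the_window_is_included(self):
        gene = self._gene(start=1_499_999)
        feats = cis_features(1_000_000, [gene], window=500_000)
        assert feats  # 499,999 bases away: inside +/-500 kb

    def test_gene_beyond_the_window_is_excluded(self):
        gene = self._gene(start=1_600_000)
        assert cis_features(1_000_000, [gene], window=500_000) == []

    def test_single_exon_gene_contributes_no_exon_tests(self):
        gene = GeneModel("G1", "chr1", {"E1": (1_000_100, 1_000_300)}, {"T1": ("E1",)})
        feats = cis_features(1_000_000, [gene])
        assert all(kind != "exon" for _, kind, _ in feats)

    def test_single_transcript_gene_contributes_no_transcript_tests(self):
        gene = GeneModel(
            "G1", "chr1",
            {"E1": (1_000_100, 1_000_300), "E2": (1_001_000, 1_001_200)},
            {"T1": ("E1", "E2")},
        )
        kinds = {kind for _, kind, _ in cis_features(1_000_000, [gene])}
        assert kinds == {"exon", "junction"}


class TestLinearModels:
    def _cohort(self, effect, n=250, seed=71, noise=0.3):
        geno = simulate_genotypes(LDBlockSpec([3], 0.5, 0.3), n, seed)
        gene = two_isoform_gene(start=int(geno.snps["pos"].max()) + 10_000)
        truth = SpliceEffectTruth(
            "snp_0001", gene.gene_id, "T_incl", 0.0, effect
        )
        expr = simulate_expression(geno, gene, truth, noise_sd=noise, seed=seed + 1)
        return geno, gene, expr

    def test_beta1_matches_the_normal_equations_oracle(self):
        geno, gene, expr = self._cohort(effect=0.5, n=40)
        g = geno.dosage("snp_0001")
        rec = exon_association(g, expr.exon_rpkm, "E2", None)
        y = rank_normalize(expr.exon_rpkm["E2"])
        loo = rank_normalize(expr.exon_rpkm[["E1", "E3"]].sum(axis=1))
        X = np.column_stack([np.ones(40), g, loo])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert rec.beta1 == pytest.approx(beta[1], abs=1e-10)

    def test_t_pvalue_matches_a_permutation_null(self):
        geno, gene, expr = self._cohort(effect=0.35, n=60, seed=73)
        g = geno.dosage("snp_0001")
        rec = exon_association(g, expr.exon_rpkm, "E2", None)
        rng = np.random.default_rng(74)
        n_perm, hits = 4_000, 0
        for _ in range(n_perm):
            perm = exon_association(rng.permutation(g), expr.exon_rpkm, "E2", None)
            hits += abs(perm.beta1 / perm.se) >= abs(rec.beta1 / rec.se)
        perm_p = (hits + 1) / (n_perm + 1)
        mc_err = 3 * np.sqrt(rec.p * (1 - rec.p) / n_perm)
        assert perm_p == pytest.approx(rec.p, abs=mc_err + 0.01)

    def test_permuted_dosage_gives_uniform_pvalues(self):
        from scipy.stats import kstest

        geno, gene, expr = self._cohort(effect=0.8, n=150, seed=75)
        g = geno.dosage("snp_0001")
        rng = np.random.default_rng(76)
        ps = [
            exon_association(rng.permutation(g), expr.exon_rpkm, "E2", None).p
            for _ in range(300)
        ]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_junction_pair_shows_opposite_effect_signs(self):
        geno, gene, expr = self._cohort(effect=0.8, n=400, seed=77, noise=0.15)
        g = geno.dosage("snp_0001")
        incl = junction_association(
            g, expr.junction_rpm["E1|E2"].to_numpy(), expr.gene.to_numpy(), None
        )
        skip = junction_association(
            g, expr.junction_rpm["E1|E3"].to_numpy(), expr.gene.to_numpy(), None
        )
        # the two junctions share donor E1 and report the same splicing shift
        # from opposite sides, so their risk-allele effects have opposite signs
        assert np.sign(incl.beta1) == -np.sign(skip.beta1)
        assert incl.p < 1e-4 and skip.p < 1e-4

    def test_transcript_test_recovers_the_affected_isoform(self):
        geno, gene, expr = self._cohort(effect=0.8, n=400, seed=78, noise=0.15)
        g = geno.dosage("snp_0001")
        rec = transcript_association(
            g, expr.transcript["T_incl"].to_numpy(), expr.gene.to_numpy(), None
        )
        assert rec.p < 1e-6 and rec.beta1 > 0

    def test_power_is_monotone_in_effect_size(self):
        rates = []
        for effect in (0.0, 0.4, 1.0):
            hits = 0
            for s in range(60):
                geno, gene, expr = self._cohort(effect, n=120, seed=1000 + s)
                rec = exon_association(
                    geno.dosage("snp_0001"), expr.exon_rpkm, "E2", None
                )
                hits += rec.p < 0.05
            rates.append(hits / 60)
        assert rates[0] <= rates[1] + 0.08 <= rates[2] + 0.08
        assert rates[2] > rates[0]

    def test_monomorphic_snp_rejected(self):
        _, gene, expr = self._cohort(effect=0.0, n=50, seed=79)
        with pytest.raises(ValueError, match="monomorphic"):
            exon_association(np.ones(50), expr.exon_rpkm, "E2", None)

    def test_collinear_design_names_the_offending_columns(self):
        geno, gene, expr = self._cohort(effect=0.0, n=50, seed=80)
        g = geno.dosage("snp_0001")
        dup = pd.DataFrame(
            {"PC1": g, "PC2": np.random.default_rng(81).normal(size=50)},
            index=expr.exon_rpkm.index,
        )
        from spliceqtl.preprocess import CovariateSet

        cov = CovariateSet(dup, pd.DataFrame(index=dup.index))
        with pytest.raises(ValueError, match="collinear"):
            exon_association(g, expr.exon_rpkm, "E2", cov)


class TestBH:
    def test_hand_worked_stepup(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_pvalues_pass_through(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_single_pvalue_is_its_own_q(self):
        assert bh_fdr([0.013]) == pytest.approx([0.013])

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.floats(1e-6, 1.0, exclude_max=False), min_size=1, max_size=40)
    )
    def test_matches_independent_stepup_oracle(self, ps):
        p = np.asarray(ps)
        m = p.size
        order = np.argsort(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]  # min over j >= i
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        assert bh_fdr(p) == pytest.approx(oracle)

    def test_assign_q_separates_families_by_default(self):
        recs = [
            _record("exon", "E1", 1.0, 0.01),
            _record("junction", "J1", 1.0, 0.04),
        ]
        per_family = assign_q(recs)
        pooled = assign_q(recs, per_family=False)
        assert per_family[0].q == pytest.approx(0.01)
        assert pooled[0].q == pytest.approx(0.02)


class TestCorroboration:
    def _gene(self):
        return two_isoform_gene(gene_id="G")

    def test_supported_transcript_hit_keeps_no_flag(self):
        gene = self._gene()
        recs = [
            _record("transcript", "T_incl", 0.5, 1e-8, q=1e-6),
            _record("junction", "E1|E2", 0.4, 1.9e-4),  # contained, same sign
        ]
        out = corroborate_transcript_hits(recs, {"G": gene})
        assert out[0].flags == set()

    def test_unsupported_transcript_hit_is_flagged(self):
        gene = self._gene()
        recs = [
            _record("transcript", "T_incl", 0.5, 1e-8, q=1e-6),
            _record("junction", "E1|E2", 0.4, 0.3),
            _record("exon", "E2", 0.4, 0.6),
        ]
        out = corroborate_transcript_hits(recs, {"G": gene})
        assert "transcript_uncorroborated" in out[0].flags

    def test_direction_inconsistent_support_does_not_count(self):
        gene = self._gene()
        # E2 is contained in T_incl but reports the opposite direction
        recs = [
            _record("transcript", "T_incl", 0.5, 1e-8, q=1e-6),
            _record("exon", "E2", -0.4, 1e-4),
        ]
        out = corroborate_transcript_hits(recs, {"G": gene})
        assert "transcript_uncorroborated" in out[0].flags

    def test_excluded_feature_with_opposite_sign_supports(self):
        gene = self._gene()
        # the skip junction E1|E3 is NOT in T_incl: opposite sign is consistent
        recs = [
            _record("transcript", "T_incl", 0.5, 1e-8, q=1e-6),
            _record("junction", "E1|E3", -0.4, 1e-4),
        ]
        out = corroborate_transcript_hits(recs, {"G": gene})
        assert out[0].flags == set()

    def test_no_transcript_hits_is_identity(self):
        recs = [_record("exon", "E2", 0.4, 0.2, q=0.4)]
        assert corroborate_transcript_hits(recs, {}) == recs


class TestParalogFlags:
    def test_listed_gene_flagged(self):
        recs = [_record("exon", "E1", 0.3, 0.01, gene="SSBP4")]
        out = flag_paralogs(recs, {"SSBP4": ["SSBP4P1"]})
        assert "paralog_suspect" in out[0].flags

    def test_empty_table_no_flags(self):
        recs = [_record("exon", "E1", 0.3, 0.01)]
        assert flag_paralogs(recs, {})[0].flags == set()

    def test_unknown_gene_warns_and_is_ignored(self):
        recs = [_record("exon", "E1", 0.3, 0.01, gene="G")]
        with pytest.warns(UserWarning, match="unknown gene"):
            out = flag_paralogs(recs, {"NOT_A_GENE": ["X"]})
        assert out[0].flags == set()
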