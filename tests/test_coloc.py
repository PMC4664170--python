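"""Fine-mapping posteriors, credible sets, and the overlap decision."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

from spliceqtl import (
    LDBlockSpec,
    SummaryStats,
    causal_log_likelihoods,
    credible_set,
    finemap_snp_filter,
    merge_snp_universe,
    overlap,
    posteriors,
    simulate_summary_stats,
    z_from_p_and_beta,
)


def _stats(z, sigma, ids=None, **meta_cols):
    ids = ids or [f"s{i}" for i in range(len(z))]
    meta = pd.DataFrame(meta_cols, index=pd.Index(ids, name="snp_id")) if meta_cols else None
    return SummaryStats(ids, np.asarray(z, float), np.asarray(sigma, float), meta)


class TestZFromP:
    def test_p_of_one_maps_to_zero(self):
        assert z_from_p_and_beta(1.0, 0.7) == 0.0
        assert z_from_p_and_beta(1.0, -0.7) == 0.0

    def test_two_sided_tail_values(self):
        assert z_from_p_and_beta(0.0455, 1.0) == pytest.approx(2.000, abs=5e-4)
        assert z_from_p_and_beta(0.05, -1.0) == pytest.approx(-1.95996, abs=1e-5)

    def test_sign_comes_from_beta(self):
        assert z_from_p_and_beta(0.01, -2.0) < 0 < z_from_p_and_beta(0.01, 2.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            z_from_p_and_beta(0.0, 1.0)
        with pytest.raises(ValueError):
            z_from_p_and_beta(0.01, 0.0)

    def test_extreme_p_stays_finite(self):
        assert np.isfinite(z_from_p_and_beta(1e-300, 1.0))


class TestCausalLogLikelihoods:
    def test_single_snp_residual_is_exactly_zero(self):
        s = _stats([2.7], [[1.0]])
        logl = causal_log_likelihoods(s, ridge=0.0)
        assert logl[0] == pytest.approx(norm.logpdf(0.0))

    def test_independent_pair_hand_algebra(self):
        # Z=(3,0), Sigma=I: residuals are (0,0) for SNP1 and (3,0) for SNP2,
        # so the likelihood ratio is exp(4.5)
        s = _stats([3.0, 0.0], np.eye(2))
        logl = causal_log_likelihoods(s, ridge=0.0)
        assert logl[0] - logl[1] == pytest.approx(4.5, abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_dense_mvn_density_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 9)
        A = rng.standard_normal((n, n + 4))
        cov = A @ A.T
        d = np.sqrt(np.diag(cov))
        sigma = cov / np.outer(d, d)
        z = rng.standard_normal(n) * 2
        s = _stats(z, sigma)
        ridge = 1e-6
        logl = causal_log_likelihoods(s, ridge=ridge)
        oracle = np.array(
            [
                multivariate_normal.logpdf(
                    z, mean=z[i] * sigma[:, i], cov=sigma + ridge * np.eye(n)
                )
                for i in range(n)
            ]
        )
        assert logl == pytest.approx(oracle, rel=1e-8)

    def test_dropping_the_constant_shifts_all_snps_equally(self):
        s = _stats([1.0, 2.0, -0.5], LDBlockSpec([3], 0.5, 0.3).correlation())
        full = causal_log_likelihoods(s, include_normalizing_constant=True)
        bare = causal_log_likelihoods(s, include_normalizing_constant=False)
        shifts = full - bare
        assert np.allclose(shifts, shifts[0])

    def test_non_pd_matrix_suggests_a_larger_ridge(self):
        sigma = np.ones((2, 2))  # perfect LD, singular
        s = _stats([1.0, 1.0], sigma)
        with pytest.raises(ValueError, match="ridge"):
            causal_log_likelihoods(s, ridge=0.0)
        causal_log_likelihoods(s, ridge=1e-6)  # regularized form works


class TestPosteriors:
    def test_single_snp_gets_everything(self):
        assert posteriors([3.2]).posteriors == pytest.approx([1.0])

    def test_symmetry_splits_evenly(self):
        assert posteriors([-1.0] * 4).posteriors == pytest.approx([0.25] * 4)

    def test_worked_independent_pair(self):
        s = _stats([3.0, 0.0], np.eye(2))
        post = posteriors(causal_log_likelihoods(s, ridge=0.0), s.snp_ids)
        assert post.posteriors[0] == pytest.approx(1 / (1 + np.exp(-4.5)), abs=1e-12)
        assert post.posteriors[0] == pytest.approx(0.9890, abs=5e-4)

    def test_additive_constant_leaves_posteriors_unchanged(self):
        logl = np.array([-3.0, -1.0, -700.0])
        a = posteriors(logl).posteriors
        b = posteriors(logl + 123.4).posteriors
        assert a == pytest.approx(b)

    def test_permutation_equivariance(self):
        logl = np.array([-3.0, -1.5, -0.2, -9.0])
        perm = [2, 0, 3, 1]
        direct = posteriors(logl).posteriors[perm]
        permuted = posteriors(logl[perm]).posteriors
        assert direct == pytest.approx(permuted)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            posteriors([])


class TestCredibleSet:
    def test_certain_snp_yields_a_singleton(self):
        cs = credible_set(posteriors([0.0]), 0.95)
        assert len(cs.snp_ids) == 1 and cs.cumulative_probability == pytest.approx(1.0)

    def test_minimal_prefix_by_brute_force(self):
        p = np.array([0.6, 0.3, 0.06, 0.04])
        post = posteriors(np.log(p), ["a", "b", "c", "d"])
        cs = credible_set(post, 0.95)
        assert cs.snp_ids == ["a", "b", "c"]
        assert cs.cumulative_probability == pytest.approx(0.96)
        # brute force: no shorter descending prefix reaches 0.95
        assert p[:2].sum() < 0.95 <= p[:3].sum()

    def test_zero_threshold_still_returns_one_snp(self):
        cs = credible_set(posteriors(np.log([0.5, 0.5])), 0.0)
        assert len(cs.snp_ids) == 1

    def test_ties_break_by_genomic_position(self):
        post = posteriors(np.log([0.5, 0.5]), ["far", "near"])
        cs = credible_set(post, 0.4, positions=[200, 100])
        assert cs.snp_ids == ["near"]


class TestOverlap:
    def test_identical_posteriors_cannot_exclude_sharing(self):
        post = posteriors(np.log([0.9, 0.07, 0.03]), ["a", "b", "c"])
        cs = credible_set(post, 0.95)
        res = overlap(cs, post)
        assert res.other_trait_cumulative >= 0.95
        assert res.decision == "shared_not_excluded"

    def test_tiny_cumulative_excludes_sharing(self):
        cs_a = credible_set(posteriors(np.log([0.97, 0.02, 0.01]), ["a", "b", "c"]), 0.95)
        post_b = posteriors(np.log([1e-9, 0.5, 0.5 - 1e-9]), ["a", "b", "c"])
        res = overlap(cs_a, post_b)
        assert res.decision == "different_causal_variant"
        assert res.other_trait_cumulative < 0.05

    def test_mismatched_universe_rejected(self):
        cs = credible_set(posteriors([0.0], ["a"]), 0.95)
        with pytest.raises(ValueError, match="absent"):
            overlap(cs, posteriors([0.0], ["b"]))


class TestMergeUniverse:
    def _pair(self):
        sigma = np.eye(3)
        a = _stats([1.0, 2.0, 3.0], sigma, ids=["r1", "r2", "r3"],
                   effect_allele=["A", "C", "G"], other_allele=["G", "T", "A"])
        b = _stats([0.5, -2.0, 1.0], sigma, ids=["r1", "r2", "r3"],
                   effect_allele=["A", "T", "G"], other_allele=["G", "C", "A"])
        return a, b

    def test_identical_panels_are_identity(self):
        a, _ = self._pair()
        out_a, out_b = merge_snp_universe(a, a)
        assert out_a.snp_ids == a.snp_ids
        assert out_a.z == pytest.approx(a.z)

    def test_disjoint_panels_rejected(self):
        a, _ = self._pair()
        b = _stats([1.0], [[1.0]], ids=["other"])
        with pytest.raises(ValueError, match="no SNPs shared"):
            merge_snp_universe(a, b)

    def test_swapped_effect_allele_flips_exactly_one_z(self):
        a, b = self._pair()
        _, out_b = merge_snp_universe(a, b)
        assert out_b.z == pytest.approx([0.5, 2.0, 1.0])  # only r2 flipped


class TestFinemapFilter:
    def test_filters_follow_the_maf_and_info_rules(self):
        meta = pd.DataFrame(
            {
                "maf": [0.0005, 0.3, 0.3, 0.3],
                "info": [0.9, 0.4, 0.9, np.nan],
            },
            index=pd.Index(["rare", "badinfo", "good", "genotyped"], name="snp_id"),
        )
        assert finemap_snp_filter(meta) == ["good", "genotyped"]


class TestCalibrationSmoke:
    def test_credible_set_usually_contains_the_causal_snp(self):
        # small-scale version of the calibration property
        sigma = LDBlockSpec([10] * 3, 0.8, 0.3).correlation()
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(60):
            causal = int(rng.integers(0, 30))
            stats = simulate_summary_stats(sigma, causal, 5.0, rng)
            post = posteriors(causal_log_likelihoods(stats), stats.snp_ids)
            cs = credible_set(post, 0.95)
            hits += stats.snp_ids[causal] in cs.snp_ids
        assert hits / 60 >= 0.85
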