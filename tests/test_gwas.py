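"""Association-scan, clumping and harmonization tests against independent
oracles (statsmodels OLS, a naive greedy clumping re-implementation)."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import primer_mr as pm
from primer_mr.fixtures import ld_block_genotypes
from primer_mr.gwas import (
    batch_marginal_assoc,
    min_p_across_factors,
    rank_inverse_normal,
    RankInverseNormal,
)
from primer_mr.simulate import default_variants, simulate_genotypes


class TestRankInverseNormal:
    def test_three_values_blom_offsets(self):
        out = rank_inverse_normal(np.array([10.0, 20.0, 30.0]))
        np.testing.assert_allclose(out, [-0.8694, 0.0, 0.8694], atol=1e-4)

    def test_median_maps_to_zero_odd_n(self, rng):
        v = rng.standard_normal(101)
        out = rank_inverse_normal(v)
        assert out[np.argsort(v)[50]] == pytest.approx(0.0, abs=1e-12)

    def test_rank_invariance_under_shuffle(self, rng):
        v = rng.standard_normal(50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(
            rank_inverse_normal(v)[perm], rank_inverse_normal(v[perm]), atol=1e-12
        )

    def test_idempotent_on_tie_free_input(self, rng):
        v = rng.standard_normal(200)
        once = rank_inverse_normal(v)
        np.testing.assert_allclose(rank_inverse_normal(once), once, atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rank_inverse_normal(np.ones(10))

    def test_fitted_transform_maps_training_values_exactly(self, rng):
        v = rng.standard_normal(100)
        t = RankInverseNormal(v)
        np.testing.assert_allclose(t(v), rank_inverse_normal(v), atol=1e-12)
        # new values interpolate monotonically
        x = np.linspace(v.min(), v.max(), 50)
        assert (np.diff(t(x)) >= 0).all()


class TestMarginalAssoc:
    def test_hand_computed_slope_intercept_only(self):
        variants = [pm.VariantMeta("rs1", 1, 100, "A", "G", 0.5)]
        G = pm.GenotypeMatrix(
            np.array([[0.0], [1.0], [2.0], [1.0]]), variants, list("abcd")
        )
        F = np.ones((4, 1))
        res = pm.marginal_assoc(np.array([0.0, 1.0, 2.0, 0.0]), G, F)
        assert res["beta"].iloc[0] == pytest.approx(1.0)

    def test_constant_phenotype_gives_null_results(self):
        variants = default_variants(5, seed=0)
        G = simulate_genotypes(50, variants, seed=0)
        res = pm.marginal_assoc(np.ones(50), G, np.ones((50, 1)))
        np.testing.assert_allclose(res["beta"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["pvalue"], 1.0)

    def test_agrees_with_joint_ols_oracle(self, rng):
        import statsmodels.api as sm

        n, s = 500, 50
        variants = default_variants(s, seed=1)
        G = simulate_genotypes(n, variants, seed=1)
        F = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.standard_normal(n) + 0.3 * G.dosages[:, 0]
        res = pm.marginal_assoc(y, G, F)
        for j in range(s):
            design = np.column_stack([G.dosages[:, j], F])
            fit = sm.OLS(y, design).fit()
            assert abs(res["beta"].iloc[j] - fit.params[0]) <= 1e-8
            assert abs(res["se"].iloc[j] - fit.bse[0]) <= 1e-8

    def test_batch_scan_matches_single_scans(self, rng):
        n, s, k = 200, 10, 3
        variants = default_variants(s, seed=2)
        G = simulate_genotypes(n, variants, seed=2)
        F = np.column_stack([np.ones(n), rng.standard_normal(n)])
        Y = rng.standard_normal((n, k))
        batch = batch_marginal_assoc(Y, G, F)
        for j in range(k):
            single = pm.marginal_assoc(Y[:, j], G, F)
            np.testing.assert_allclose(batch[j]["beta"], single["beta"], atol=1e-12)
            np.testing.assert_allclose(batch[j]["se"], single["se"], atol=1e-12)

    def test_null_pvalues_uniform(self, rng):
        n, s = 300, 2000
        variants = default_variants(s, seed=3)
        G = simulate_genotypes(n, variants, seed=3)
        y = rng.standard_normal(n)
        res = pm.marginal_assoc(y, G, np.ones((n, 1)))
        ks = kstest(res["pvalue"], "uniform").statistic
        assert ks < 1.63 / np.sqrt(s)  # 1% critical value


class TestMinP:
    def test_single_scan_identity(self, small_pipeline):
        scans = small_pipeline["scans"][:1]
        minp = min_p_across_factors(scans)
        np.testing.assert_allclose(minp["min_pvalue"], scans[0]["pvalue"])

    def test_elementwise_minimum_and_argmin(self):
        ids = ["rs1"]
        scans = [
            pd.DataFrame({"variant_id": ids, "beta": [0.0], "se": [1.0], "pvalue": [p]})
            for p in (0.3, 1e-9, 0.01)
        ]
        minp = min_p_across_factors(scans)
        assert minp["min_pvalue"].iloc[0] == 1e-9
        assert minp["argmin_factor"].iloc[0] == 1

    def test_mismatched_variant_lists_rejected(self):
        a = pd.DataFrame({"variant_id": ["rs1"], "pvalue": [0.5]})
        b = pd.DataFrame({"variant_id": ["rs2"], "pvalue": [0.5]})
        with pytest.raises(ValueError):
            min_p_across_factors([a, b])


from tests_support_clump import clump_oracle as _clump_oracle  # noqa: E402


class TestClump:
    def test_empty_when_nothing_significant(self, small_pipeline):
        minp = small_pipeline["minp"].copy()
        minp["min_pvalue"] = 0.5
        inst = pm.clump(minp, small_pipeline["exposure"].genotypes)
        assert len(inst) == 0

    def test_hand_worked_three_variant_case(self):
        # A and B correlated on chr1 within the window; C on another chromosome
        rng = np.random.default_rng(0)
        a = rng.binomial(2, 0.4, 500).astype(float)
        noise = rng.binomial(1, 0.1, 500)
        b = np.clip(a + noise - rng.binomial(1, 0.1, 500), 0, 2).astype(float)
        c = rng.binomial(2, 0.4, 500).astype(float)
        variants = [
            pm.VariantMeta("A", 1, 100_000, "A", "G", 0.4),
            pm.VariantMeta("B", 1, 200_000, "C", "T", 0.4),
            pm.VariantMeta("C", 2, 100_000, "A", "G", 0.4),
        ]
        G = pm.GenotypeMatrix(
            np.column_stack([a, b, c]), variants, [f"i{i}" for i in range(500)]
        )
        assert np.corrcoef(a, b)[0, 1] ** 2 > 0.05
        minp = pd.DataFrame(
            {"variant_id": ["A", "B", "C"], "min_pvalue": [1e-10, 1e-9, 1e-8]}
        )
        inst = pm.clump(minp, G, p_thresh=5e-8, r2_cutoff=0.05, window_kb=5000)
        assert inst.variant_ids == ["A", "C"]
        assert "B" in inst.removed

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle_on_ld_blocks(self, seed):
        G, _ = ld_block_genotypes(400, seed=seed)
        rng = np.random.default_rng(seed)
        minp = pd.DataFrame(
            {
                "variant_id": G.variant_ids,
                "min_pvalue": 10.0 ** rng.uniform(-12, -4, G.n_variants),
            }
        )
        inst = pm.clump(minp, G, p_thresh=5e-8, r2_cutoff=0.05, window_kb=500)
        oracle = _clump_oracle(minp, G, 5e-8, 0.05, 500)
        assert inst.variant_ids == oracle

    def test_selected_set_satisfies_invariants(self, small_pipeline):
        inst = small_pipeline["instruments"]
        G = small_pipeline["exposure"].genotypes
        assert all(p < inst.p_thresh for p in inst.min_pvalues)
        meta = {v.variant_id: v for v in G.variants}
        col = {v.variant_id: j for j, v in enumerate(G.variants)}
        for i, a in enumerate(inst.variant_ids):
            for b in inst.variant_ids[i + 1 :]:
                va, vb = meta[a], meta[b]
                if va.chromosome != vb.chromosome:
                    continue
                if abs(va.position - vb.position) > inst.window_kb * 1000:
                    continue
                r2 = np.corrcoef(G.dosages[:, col[a]], G.dosages[:, col[b]])[0, 1] ** 2
                assert r2 <= inst.r2_cutoff


class TestHarmonize:
    def _stats(self, rows):
        return pd.DataFrame(
            rows,
            columns=["variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue"],
        )

    def test_swapped_alleles_flip_sign(self):
        exp = [pm.VariantMeta("rs1", 1, 100, "A", "G", 0.3)]
        stats = self._stats([["rs1", "G", "A", 0.5, 0.1, 0.01]])
        aligned, _ = pm.harmonize(exp, stats)
        assert aligned["beta"].iloc[0] == pytest.approx(-0.5)

    def test_palindromic_variant_dropped(self):
        exp = [pm.VariantMeta("rs1", 1, 100, "A", "T", 0.3)]
        stats = self._stats([["rs1", "A", "T", 0.5, 0.1, 0.01]])
        aligned, log = pm.harmonize(exp, stats)
        assert len(aligned) == 0
        assert log["reason"].iloc[0] == "palindromic"

    def test_allele_mismatch_dropped(self):
        exp = [pm.VariantMeta("rs1", 1, 100, "A", "G", 0.3)]
        stats = self._stats([["rs1", "A", "C", 0.5, 0.1, 0.01]])
        aligned, log = pm.harmonize(exp, stats)
        assert len(aligned) == 0
        assert "mismatch" in log["reason"].iloc[0]

    def test_idempotent(self, small_pipeline):
        exposure = small_pipeline["exposure"]
        once = small_pipeline["stats"]
        twice, _ = pm.harmonize(exposure.genotypes.variants, once)
        pd.testing.assert_frame_equal(
            twice.reset_index(drop=True), once.reset_index(drop=True)
        )
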