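"""Generative-model tests: genotypes, factor heritability, warping, variance
bookkeeping and the two-sample split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import primer_mr as pm
from primer_mr.simulate import (
    LDBlockSpec,
    default_variants,
    simulate_genotypes,
    simulate_risk_factors,
    simulate_covariates,
    warp_contribution,
)


class TestGenotypes:
    def test_dosage_mean_matches_allele_frequency(self):
        variants = [pm.VariantMeta("rs1", 1, 1000, "A", "G", 0.5)]
        G = simulate_genotypes(1000, variants, seed=1)
        assert 0.9 <= G.dosages[:, 0].mean() <= 1.1  # E[dosage] = 2*maf = 1

    def test_ld_block_raises_pairwise_correlation(self):
        variants = [
            pm.VariantMeta("rs1", 1, 1_000_000, "A", "G", 0.3),
            pm.VariantMeta("rs2", 1, 1_100_000, "C", "T", 0.3),
        ]
        spec = LDBlockSpec(blocks=((0, 1),), rho=0.9)
        r2_ld, r2_ind = [], []
        for seed in range(5):
            Gl = simulate_genotypes(1000, variants, ld_blocks=spec, seed=seed)
            Gi = simulate_genotypes(1000, variants, seed=seed + 100)
            r2_ld.append(np.corrcoef(Gl.dosages.T)[0, 1] ** 2)
            r2_ind.append(np.corrcoef(Gi.dosages.T)[0, 1] ** 2)
        assert np.mean(r2_ld) > np.mean(r2_ind)
        assert np.mean(r2_ld) > 0.3

    def test_deterministic_under_seed(self):
        variants = default_variants(10, seed=0)
        a = simulate_genotypes(200, variants, seed=42)
        b = simulate_genotypes(200, variants, seed=42)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_rejects_tiny_cohort_and_bad_maf(self):
        variants = default_variants(3, seed=0)
        with pytest.raises(ValueError):
            simulate_genotypes(1, variants, seed=0)
        with pytest.raises(ValueError):
            pm.VariantMeta("rs1", 1, 1, "A", "G", 0.7)
        with pytest.raises(ValueError):
            pm.VariantMeta("rs1", 1, 1, "A", "A", 0.3)

    def test_columns_polymorphic(self, small_cohort):
        cohort, _, _ = small_cohort
        assert (cohort.genotypes.dosages.std(axis=0) > 0).all()


class TestRiskFactors:
    def test_heritability_fraction_realized(self):
        cfg = pm.SimulationConfig(
            n_individuals=5000, n_variants=60, n_factors=2, n_causal_factors=1,
            variants_per_factor=20, factor_heritability=0.5,
            var_explained_risk=0.3, seed=3,
        )
        variants = default_variants(cfg.n_variants, seed=cfg.seed)
        G = simulate_genotypes(cfg.n_individuals, variants, seed=cfg.seed)
        X, effects = simulate_risk_factors(G, cfg)
        for j in range(cfg.n_factors):
            idx = np.flatnonzero(effects[:, j])
            score = G.dosages[:, idx] @ effects[idx, j]
            r2 = np.corrcoef(score, X[:, j])[0, 1] ** 2
            assert 0.45 <= r2 <= 0.55

    def test_low_heritability_limit(self):
        cfg = pm.SimulationConfig(
            n_individuals=3000, n_variants=30, n_factors=1, n_causal_factors=1,
            variants_per_factor=10, factor_heritability=0.01,
            var_explained_risk=0.3, seed=5,
        )
        variants = default_variants(cfg.n_variants, seed=cfg.seed)
        G = simulate_genotypes(cfg.n_individuals, variants, seed=cfg.seed)
        X, effects = simulate_risk_factors(G, cfg)
        idx = np.flatnonzero(effects[:, 0])
        slopes = [
            np.polyfit(G.dosages[:, i], X[:, 0], 1)[0] for i in idx[:5]
        ]
        assert np.max(np.abs(slopes)) < 0.15

    def test_rejects_bad_heritability(self):
        with pytest.raises(ValueError):
            pm.SimulationConfig(factor_heritability=1.0)


class TestWarp:
    def test_negligible_below_threshold(self):
        for s in (0.5, 2.0, 8.0):
            lo = warp_contribution(1.0 - 10 / s, 1.0, s)
            hi = warp_contribution(1.0 + 10 / s, 1.0, s)
            assert lo < 0.01 * hi

    def test_linear_regime_slope_equals_sharpness(self):
        for s in (0.5, 2.0):
            d = warp_contribution(101.0, 1.0, s) - warp_contribution(100.0, 1.0, s)
            assert d == pytest.approx(s, rel=1e-6)

    def test_saturation_bounds_output(self):
        x = np.linspace(-5, 500, 200)
        y = warp_contribution(x, 0.0, 2.0, saturation=3.0)
        assert (y <= 3.0 + 1e-12).all()
        assert y[-1] == pytest.approx(3.0, rel=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        t=st.floats(-3, 3),
        s=st.floats(0.1, 10),
        sat=st.one_of(st.none(), st.floats(0.1, 10)),
    )
    def test_monotone_nondecreasing(self, t, s, sat):
        x = np.linspace(-10, 10, 401)
        y = warp_contribution(x, t, s, saturation=sat)
        assert (np.diff(y) >= -1e-12).all()


class TestOutcome:
    def test_variance_fractions_match_request(self):
        cfg = pm.SimulationConfig(
            n_individuals=6000, n_variants=80, n_factors=4, n_causal_factors=2,
            variants_per_factor=20, var_explained_risk=0.3,
            var_explained_pleiotropy=0.1, pleiotropic_variant_fraction=0.2, seed=9,
        )
        _, _, truth = pm.simulate_cohort(cfg)
        vr, vp, vn = truth.realized_variance_fractions
        assert vr == pytest.approx(0.3, abs=0.02)
        assert vp == pytest.approx(0.1, abs=0.02)
        assert vr + vp + vn == pytest.approx(1.0, abs=0.02)

    def test_null_scenario_outcome_independent_of_factors(self):
        cors = []
        for seed in range(10):
            cfg = pm.SimulationConfig(
                n_individuals=2000, n_variants=40, n_factors=3, n_causal_factors=0,
                var_explained_risk=0.0, variants_per_factor=12, seed=seed,
            )
            cohort, outcome, truth = pm.simulate_cohort(cfg)
            assert np.ptp(truth.aggregate_risk) == 0.0
            for j in range(3):
                cors.append(pm.spearman_corr(cohort.risk_factors[:, j], outcome))
        assert np.mean(np.abs(cors)) < 2 / np.sqrt(2000)

    def test_pleiotropy_hits_only_pleiotropic_variants(self):
        cfg = pm.SimulationConfig(
            n_individuals=6000, n_variants=60, n_factors=2, n_causal_factors=1,
            variants_per_factor=15, var_explained_risk=0.2,
            var_explained_pleiotropy=0.2, pleiotropic_variant_fraction=0.25, seed=4,
        )
        cohort, outcome, truth = pm.simulate_cohort(cfg)
        resid = outcome - truth.aggregate_risk
        G = cohort.genotypes.dosages
        pleio = set(truth.pleiotropic_variants.tolist())
        z = []
        for s in range(G.shape[1]):
            g = G[:, s] - G[:, s].mean()
            b = g @ resid / (g @ g)
            se = resid.std() / np.sqrt(g @ g)
            z.append((s in pleio, abs(b / se)))
        z_p = [v for is_p, v in z if is_p]
        z_n = [v for is_p, v in z if not is_p]
        assert np.mean(z_p) > 3 * np.mean(z_n)

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(ValueError):
            pm.SimulationConfig(var_explained_risk=0.7, var_explained_pleiotropy=0.4)

    def test_bit_identical_under_same_config(self, small_config):
        c1, o1, _ = pm.simulate_cohort(small_config)
        c2, o2, _ = pm.simulate_cohort(small_config)
        np.testing.assert_array_equal(c1.genotypes.dosages, c2.genotypes.dosages)
        np.testing.assert_array_equal(c1.risk_factors, c2.risk_factors)
        np.testing.assert_array_equal(o1, o2)


class TestSplit:
    def _cohort(self, n, seed=0):
        variants = default_variants(6, seed=seed)
        G = simulate_genotypes(n, variants, seed=seed)
        F = simulate_covariates(n, seed=seed)
        X = np.random.default_rng(seed).standard_normal((n, 2))
        return pm.CohortData(G, X, F, ["f1", "f2"])

    def test_even_split_is_disjoint_partition(self):
        cohort = self._cohort(100)
        outcome = np.arange(100.0)
        exp, (out, y_out) = pm.split_two_sample(cohort, outcome, seed=0)
        ids_e = set(exp.genotypes.sample_ids)
        ids_o = set(out.genotypes.sample_ids)
        assert len(ids_e) == len(ids_o) == 50
        assert not ids_e & ids_o
        assert ids_e | ids_o == set(cohort.genotypes.sample_ids)

    def test_odd_n_extra_individual_goes_to_exposure(self):
        cohort = self._cohort(101)
        exp, (out, _) = pm.split_two_sample(cohort, np.zeros(101), seed=1)
        assert exp.n_samples == 51 and out.n_samples == 50

    def test_same_seed_same_split(self):
        cohort = self._cohort(60)
        e1, (o1, y1) = pm.split_two_sample(cohort, np.arange(60.0), seed=5)
        e2, (o2, y2) = pm.split_two_sample(cohort, np.arange(60.0), seed=5)
        assert e1.genotypes.sample_ids == e2.genotypes.sample_ids
        np.testing.assert_array_equal(y1, y2)
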