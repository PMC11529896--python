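import numpy as np
import pytest

import primer_mr as pm
from primer_mr.gwas import (
    batch_marginal_assoc,
    min_p_across_factors,
    outcome_summary_from_cohort,
    harmonize,
    rank_inverse_normal,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A quick but non-trivial simulation: strong signal, modest size."""
    return pm.SimulationConfig(
        n_individuals=1200,
        n_variants=40,
        n_factors=3,
        n_causal_factors=2,
        variants_per_factor=12,
        factor_heritability=0.4,
        var_explained_risk=0.4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, outcome, truth = pm.simulate_cohort(small_config)
    return cohort, outcome, truth


@pytest.fixture(scope="session")
def small_split(small_cohort, small_config):
    cohort, outcome, truth = small_cohort
    exposure, (out_cohort, y_out), (rows_exp, rows_out) = pm.split_two_sample(
        cohort, outcome, seed=small_config.seed, truth=truth
    )
    return exposure, out_cohort, y_out, rows_exp, truth


@pytest.fixture(scope="session")
def small_pipeline(small_split):
    """Instrument selection + harmonized outcome stats on the small cohort."""
    exposure, out_cohort, y_out, rows_exp, truth = small_split
    k = exposure.risk_factors.shape[1]
    Xr = np.column_stack(
        [rank_inverse_normal(exposure.risk_factors[:, j]) for j in range(k)]
    )
    scans = batch_marginal_assoc(Xr, exposure.genotypes, exposure.covariates)
    minp = min_p_across_factors(scans)
    instruments = pm.clump(minp, exposure.genotypes)
    raw_stats = outcome_summary_from_cohort(
        y_out, out_cohort.genotypes, out_cohort.covariates
    )
    aligned, _ = harmonize(exposure.genotypes.variants, raw_stats)
    return {
        "exposure": exposure,
        "scans": scans,
        "minp": minp,
        "instruments": instruments,
        "stats": aligned,
        "rows_exp": rows_exp,
        "truth": truth,
    }
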