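"""Canned seeded scenarios: small, complete cohorts for tests and demos.

Each fixture writes a cohort directory (exposure cohort TSVs plus the
harmonizable outcome summary statistics computed on the disjoint outcome
cohort) so every downstream command can run on it directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ._utils import stream_rng
from .gwas import outcome_summary_from_cohort
from .io import write_cohort, write_summary_stats
from .simulate import (
    LDBlockSpec,
    SimulationConfig,
    VariantMeta,
    default_variants,
    simulate_genotypes,
    simulate_cohort,
    split_two_sample,
)

__all__ = ["FIXTURES", "make_fixture", "fixture_config", "ld_block_genotypes"]

# scenario registry: knobs only, all small enough for quick pipelines
FIXTURES: dict[str, SimulationConfig] = {
    "tiny": SimulationConfig(
        n_individuals=600, n_variants=40, n_factors=3, n_causal_factors=2,
        variants_per_factor=12, factor_heritability=0.4, var_explained_risk=0.4,
    ),
    "standard": SimulationConfig(),
    "null": SimulationConfig(
        n_individuals=2000, n_variants=80, n_factors=5, n_causal_factors=0,
        var_explained_risk=0.0, variants_per_factor=16,
    ),
    "pleiotropy": SimulationConfig(
        n_individuals=2000, n_variants=80, n_factors=5, n_causal_factors=3,
        variants_per_factor=16, var_explained_pleiotropy=0.1,
        pleiotropic_variant_fraction=0.2,
    ),
    # warp threshold far below the observed range makes the softplus ramp
    # effectively the identity, so the generative model is linear
    "linear": SimulationConfig(
        n_individuals=4000, n_variants=100, n_factors=5, n_causal_factors=5,
        variants_per_factor=20, var_explained_risk=0.6,
        warp_threshold=-10.0, warp_sharpness=1.0,
    ),
    "ld-blocks": SimulationConfig(
        n_individuals=1500, n_variants=30, n_factors=2, n_causal_factors=1,
        variants_per_factor=10, var_explained_risk=0.3,
    ),
}


def fixture_config(name: str, seed: int) -> SimulationConfig:
    if name not in FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; valid names: {sorted(FIXTURES)}"
        )
    return FIXTURES[name].replace(seed=int(seed))


def ld_block_genotypes(n: int, seed: int, n_blocks: int = 6, block_size: int = 5,
                       rho: float = 0.8):
    """Genotypes with tight LD blocks of nearby variants, for clumping tests."""
    variants = []
    i = 0
    for b in range(n_blocks):
        for t in range(block_size):
            variants.append(
                VariantMeta(
                    variant_id=f"rsld{i + 1:04d}",
                    chromosome=b % 4 + 1,
                    position=(b // 4) * 60_000_000 + t * 100_000 + 1_000_000,
                    effect_allele="A",
                    other_allele="G",
                    maf=0.3,
                )
            )
            i += 1
    blocks = tuple(
        tuple(range(b * block_size, (b + 1) * block_size)) for b in range(n_blocks)
    )
    spec = LDBlockSpec(blocks=blocks, rho=rho)
    return simulate_genotypes(n, variants, ld_blocks=spec, seed=seed), spec


def make_fixture(name: str, seed: int, outdir) -> Path:
    """Write a complete fixture directory for the named scenario.

    The exposure cohort (with its simulated outcome and true risk for
    evaluation) is written as cohort TSVs; outcome summary statistics are
    computed on the disjoint outcome cohort and written as
    ``outcome_stats.tsv``.
    """
    cfg = fixture_config(name, seed)
    outdir = Path(outdir)
    cohort, outcome, truth = simulate_cohort(cfg)

    if name == "ld-blocks":
        # replace the independent genotypes with LD-structured ones
        G, _ = ld_block_genotypes(cfg.n_individuals, seed=cfg.seed)
        ids = cohort.genotypes.sample_ids
        G.sample_ids = ids
        cohort.genotypes = G
        # keep phenotypes as simulated; only the clumping surface changes

    exposure, (out_cohort, y_out), (rows_exp, _) = split_two_sample(
        cohort, outcome, seed=cfg.seed, truth=truth
    )
    stats = outcome_summary_from_cohort(
        y_out, out_cohort.genotypes, out_cohort.covariates
    )
    write_cohort(exposure, outdir, outcome=outcome[rows_exp])
    write_summary_stats(stats, outdir / "outcome_stats.tsv")
    np.savetxt(
        outdir / "true_risk.tsv",
        np.column_stack([truth.aggregate_risk[rows_exp]]),
        header="aggregate_risk",
        comments="",
    )
    return outdir
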