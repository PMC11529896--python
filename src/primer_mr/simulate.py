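"""Synthetic genetic cohorts for two-sample Mendelian randomization studies.

Generates genotype dosage matrices in Hardy-Weinberg equilibrium (optionally
with equicorrelated LD blocks), heritable risk factors driven by sparse
variant effects, and a continuous health outcome composed of nonlinearly
warped causal risk-factor contributions, a horizontal-pleiotropy term and
Gaussian noise, with empirically exact variance fractions.

The warping of each causal factor is a smooth thresholded ramp: negligible
below a threshold, then increasing with a configurable slope (sharpness),
optionally approaching a finite asymptote (saturation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._utils import standardize, stream_rng

__all__ = [
    "VariantMeta",
    "GenotypeMatrix",
    "CohortData",
    "SimulationConfig",
    "SimulationTruth",
    "LDBlockSpec",
    "default_variants",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_risk_factors",
    "warp_contribution",
    "simulate_outcome",
    "simulate_cohort",
    "split_two_sample",
]

# Non-palindromic allele pairs cycled through when inventing variant metadata.
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass(frozen=True)
class VariantMeta:
    """Identity and population frequency of one biallelic variant."""

    variant_id: str
    chromosome: int
    position: int
    effect_allele: str
    other_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.variant_id}: maf {self.maf} outside (0, 0.5]")
        if self.chromosome < 1 or self.position < 1:
            raise ValueError(f"{self.variant_id}: invalid coordinates")

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class GenotypeMatrix:
    """N x S additive dosage matrix with per-variant metadata."""

    dosages: np.ndarray
    variants: list[VariantMeta]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        n, s = self.dosages.shape
        if s != len(self.variants):
            raise ValueError("column count does not match variant metadata")
        if n != len(self.sample_ids):
            raise ValueError("row count does not match sample ids")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def subset_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {v.variant_id: j for j, v in enumerate(self.variants)}
        cols = [index[i] for i in ids]
        return GenotypeMatrix(
            dosages=self.dosages[:, cols],
            variants=[self.variants[j] for j in cols],
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, rows: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[rows],
            variants=list(self.variants),
            sample_ids=[self.sample_ids[i] for i in rows],
        )


@dataclass
class CohortData:
    """Individual-level data: genotypes G, risk factors X, covariates F."""

    genotypes: GenotypeMatrix
    risk_factors: np.ndarray
    covariates: np.ndarray
    factor_names: list[str]

    def __post_init__(self) -> None:
        self.risk_factors = np.asarray(self.risk_factors, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        n = self.genotypes.n_samples
        if self.risk_factors.shape[0] != n or self.covariates.shape[0] != n:
            raise ValueError("row counts of genotypes, factors and covariates differ")
        if self.risk_factors.shape[1] != len(self.factor_names):
            raise ValueError("factor_names length does not match risk factor columns")
        const = [
            j
            for j in range(self.covariates.shape[1])
            if np.ptp(self.covariates[:, j]) == 0.0 and self.covariates[0, j] != 0.0
        ]
        if len(const) != 1:
            raise ValueError("covariates must contain exactly one constant (intercept) column")

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples

    def subset_samples(self, rows: np.ndarray) -> "CohortData":
        return CohortData(
            genotypes=self.genotypes.subset_samples(rows),
            risk_factors=self.risk_factors[rows],
            covariates=self.covariates[rows],
            factor_names=list(self.factor_names),
        )


@dataclass(frozen=True)
class LDBlockSpec:
    """Partition of variant indices into blocks with within-block correlation rho."""

    blocks: tuple[tuple[int, ...], ...]
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        flat = [i for b in self.blocks for i in b]
        if len(flat) != len(set(flat)):
            raise ValueError("LD blocks must be disjoint")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulation study.

    ``n_individuals`` is the total cohort size before the even two-sample
    split; each of the exposure and outcome cohorts receives half.
    ``var_explained_risk``/``var_explained_pleiotropy`` are the fractions of
    outcome variance carried by the warped causal risk factors and by the
    direct (pleiotropic) genetic contribution, the remainder being noise.
    """

    n_individuals: int = 8000
    n_variants: int = 200
    n_factors: int = 10
    n_causal_factors: int = 5
    var_explained_risk: float = 0.3
    var_explained_pleiotropy: float = 0.0
    pleiotropic_variant_fraction: float = 0.1
    warp_threshold: float = 0.5
    warp_sharpness: float = 2.0
    warp_saturation: Optional[float] = None
    variants_per_factor: int = 20
    factor_heritability: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if not (0 <= self.n_causal_factors <= self.n_factors):
            raise ValueError("n_causal_factors outside [0, n_factors]")
        if self.var_explained_risk + self.var_explained_pleiotropy >= 1.0:
            raise ValueError("variance fractions must sum to less than 1")
        if not (0.0 <= self.var_explained_risk < 1.0):
            raise ValueError("var_explained_risk outside [0, 1)")
        if not (0.0 <= self.var_explained_pleiotropy < 1.0):
            raise ValueError("var_explained_pleiotropy outside [0, 1)")
        if self.n_causal_factors == 0 and self.var_explained_risk != 0.0:
            raise ValueError("null scenario (no causal factors) requires var_explained_risk=0")
        if not (0.0 < self.factor_heritability < 1.0):
            raise ValueError("factor_heritability outside (0, 1)")
        if self.warp_sharpness <= 0:
            raise ValueError("warp_sharpness must be positive")
        if self.warp_saturation is not None and self.warp_saturation < 0:
            raise ValueError("warp_saturation must be nonnegative")
        if self.variants_per_factor < 1:
            raise ValueError("variants_per_factor must be positive")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort, used for evaluation."""

    aggregate_risk: np.ndarray
    causal_factors: np.ndarray
    per_factor_warp_params: dict[int, tuple[float, float, Optional[float]]]
    pleiotropic_variants: np.ndarray
    genetic_factor_effects: np.ndarray
    realized_variance_fractions: tuple[float, float, float] = field(default=(0.0, 0.0, 1.0))


def default_variants(
    n_variants: int,
    seed: int = 0,
    spacing_bp: int = 11_000_000,
    n_chromosomes: int = 22,
) -> list[VariantMeta]:
    """Invent variant metadata spread over chromosomes.

    Default spacing places consecutive variants on a chromosome outside a
    +/-5000 kb clumping window, so distance alone never links independently
    drawn variants.
    """
    rng = stream_rng(seed, "variant-meta")
    mafs = rng.uniform(0.1, 0.5, size=n_variants)
    variants = []
    per_chrom = -(-n_variants // n_chromosomes)
    for i in range(n_variants):
        chrom = i // per_chrom + 1
        pos = (i % per_chrom) * spacing_bp + 1_000_000
        ea, oa = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        variants.append(
            VariantMeta(
                variant_id=f"rs{i + 1:06d}",
                chromosome=chrom,
                position=pos,
                effect_allele=ea,
                other_allele=oa,
                maf=float(mafs[i]),
            )
        )
    return variants


def simulate_genotypes(
    n: int,
    variants: Sequence[VariantMeta],
    ld_blocks: Optional[LDBlockSpec] = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw additive dosages under Hardy-Weinberg equilibrium.

    Each dosage is the sum of two Bernoulli(maf) haplotype draws. Within an
    LD block, haplotype draws share a Gaussian-copula latent factor with
    equicorrelation rho, so realized pairwise r^2 grows monotonically with
    rho; variants outside blocks are independent.
    """
    from scipy.special import ndtri

    if n < 2:
        raise ValueError("cohort must contain at least 2 individuals")
    rng = stream_rng(seed, "genotypes")
    s = len(variants)
    mafs = np.array([v.maf for v in variants])
    thresholds = ndtri(mafs)  # P(z < t) = maf

    in_block = np.zeros(s, dtype=bool)
    # latent normals per haplotype copy
    haplos = np.empty((2, n, s))
    for copy in range(2):
        z = rng.standard_normal((n, s))
        if ld_blocks is not None and ld_blocks.rho > 0:
            r = np.sqrt(ld_blocks.rho)
            for block in ld_blocks.blocks:
                idx = np.asarray(block, dtype=int)
                in_block[idx] = True
                shared = rng.standard_normal(n)
                z[:, idx] = r * shared[:, None] + np.sqrt(1 - ld_blocks.rho) * z[:, idx]
        haplos[copy] = z
    dosages = (haplos < thresholds[None, None, :]).sum(axis=0).astype(float)

    # reject degenerate columns outside LD blocks (monomorphic draws)
    var0 = dosages.std(axis=0) == 0.0
    if var0.any():
        # resample the offending independent columns until polymorphic
        for j in np.flatnonzero(var0 & ~in_block):
            for _ in range(100):
                col = (rng.random((2, n)) < mafs[j]).sum(axis=0).astype(float)
                if col.std() > 0:
                    dosages[:, j] = col
                    break
            else:
                raise RuntimeError(f"variant {variants[j].variant_id} persistently monomorphic")
    sample_ids = [f"ind{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, variants=list(variants), sample_ids=sample_ids)


def simulate_covariates(n: int, seed: int = 0, n_nuisance: int = 2) -> np.ndarray:
    """Intercept column plus standard-normal nuisance covariates."""
    rng = stream_rng(seed, "covariates")
    return np.column_stack([np.ones(n), rng.standard_normal((n, n_nuisance))])


def simulate_risk_factors(
    G: GenotypeMatrix,
    config: SimulationConfig,
    covariates: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate heritable risk factors from sparse variant effects.

    Each factor is a genetic score over its assigned variants plus Gaussian
    noise, empirically rescaled so the score explains ``factor_heritability``
    of the factor's variance. Nuisance covariates (if provided) add a small
    extra contribution. Returns (risk_factors, genetic_factor_effects).
    """
    cfg = config
    rng = stream_rng(cfg.seed, "risk-factors")
    n, s = G.dosages.shape
    k = cfg.n_factors
    h2 = cfg.factor_heritability

    # assign variant blocks to factors; disjoint while the pool lasts, then wrap
    perm = rng.permutation(s)
    effects = np.zeros((s, k))
    X = np.empty((n, k))
    for j in range(k):
        start = (j * cfg.variants_per_factor) % s
        idx = perm[[(start + t) % s for t in range(cfg.variants_per_factor)]]
        idx = np.unique(idx)
        beta = rng.standard_normal(idx.size)
        effects[idx, j] = beta
        score = standardize(G.dosages[:, idx] @ beta)
        noise = standardize(rng.standard_normal(n))
        X[:, j] = np.sqrt(h2) * score + np.sqrt(1 - h2) * noise
        if covariates is not None and covariates.shape[1] > 1:
            w = rng.normal(0.0, 1.0, size=covariates.shape[1] - 1)
            X[:, j] += 0.1 * (covariates[:, 1:] @ w)
    return X, effects


def warp_contribution(
    x,
    threshold: float,
    sharpness: float,
    saturation: Optional[float] = None,
):
    """Smooth thresholded-ramp warping of a single risk factor.

    softplus(sharpness * (x - threshold)): approximately 0 far below the
    threshold, slope approaching ``sharpness`` far above it. With finite
    ``saturation`` s the ramp is passed through s*tanh(u/s), giving a bounded
    monotone curve with asymptote s. Differentiable everywhere.
    """
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    z = sharpness * (np.asarray(x, dtype=float) - threshold)
    ramp = np.logaddexp(0.0, z)  # softplus, overflow-safe
    if saturation is None:
        return ramp
    if saturation < 0:
        raise ValueError("saturation must be nonnegative")
    if saturation == 0.0:
        return np.zeros_like(ramp)
    return saturation * np.tanh(ramp / saturation)


def simulate_outcome(
    cohort: CohortData,
    config: SimulationConfig,
) -> tuple[np.ndarray, SimulationTruth]:
    """Compose the outcome from warped causal factors, pleiotropy and noise.

    Each component is empirically orthogonalized against the preceding ones,
    standardized, and scaled to the square root of its requested variance
    fraction, so the realized fractions match the request essentially exactly
    in-sample.
    """

    def _orthogonalize(v: np.ndarray, others: list[np.ndarray]) -> np.ndarray:
        basis = np.column_stack([np.ones_like(v)] + others)
        coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
        return v - basis @ coef

    cfg = config
    vr, vp = cfg.var_explained_risk, cfg.var_explained_pleiotropy
    if vr + vp >= 1.0:
        raise ValueError("variance fractions must sum to less than 1")
    rng = stream_rng(cfg.seed, "outcome")
    n = cohort.n_samples
    s = cohort.genotypes.n_variants
    X = cohort.risk_factors

    causal = np.sort(rng.choice(cfg.n_factors, size=cfg.n_causal_factors, replace=False))
    warp_params = {
        int(k): (cfg.warp_threshold, cfg.warp_sharpness, cfg.warp_saturation) for k in causal
    }
    if cfg.n_causal_factors > 0:
        raw = sum(
            warp_contribution(X[:, k], *warp_params[int(k)]) for k in causal
        )
        risk = np.sqrt(vr) * standardize(raw)
    else:
        risk = np.zeros(n)

    if vp > 0 and cfg.pleiotropic_variant_fraction > 0:
        m = max(1, round(cfg.pleiotropic_variant_fraction * s))
        pleio_idx = np.sort(rng.choice(s, size=m, replace=False))
        beta_p = rng.standard_normal(m)
        pleio_raw = cohort.genotypes.dosages[:, pleio_idx] @ beta_p
        if vr > 0:
            pleio_raw = _orthogonalize(pleio_raw, [risk])
        pleio = np.sqrt(vp) * standardize(pleio_raw)
    else:
        pleio_idx = np.array([], dtype=int)
        pleio = np.zeros(n)

    noise_raw = _orthogonalize(
        rng.standard_normal(n), [c for c in (risk, pleio) if c.std() > 0]
    )
    noise = np.sqrt(1.0 - vr - vp) * standardize(noise_raw)
    outcome = risk + pleio + noise

    tot = outcome.var()
    realized = (
        float(risk.var() / tot),
        float(pleio.var() / tot),
        float(noise.var() / tot),
    )
    truth = SimulationTruth(
        aggregate_risk=risk,
        causal_factors=causal,
        per_factor_warp_params=warp_params,
        pleiotropic_variants=pleio_idx,
        genetic_factor_effects=np.zeros((s, cfg.n_factors)),
        realized_variance_fractions=realized,
    )
    return outcome, truth


def simulate_cohort(config: SimulationConfig) -> tuple[CohortData, np.ndarray, SimulationTruth]:
    """Full generative pipeline: variants -> genotypes -> factors -> outcome."""
    cfg = config
    variants = default_variants(cfg.n_variants, seed=cfg.seed)
    G = simulate_genotypes(cfg.n_individuals, variants, seed=cfg.seed)
    F = simulate_covariates(cfg.n_individuals, seed=cfg.seed)
    X, effects = simulate_risk_factors(G, cfg, covariates=F)
    cohort = CohortData(
        genotypes=G,
        risk_factors=X,
        covariates=F,
        factor_names=[f"factor_{k + 1}" for k in range(cfg.n_factors)],
    )
    outcome, truth = simulate_outcome(cohort, cfg)
    truth.genetic_factor_effects = effects
    return cohort, outcome, truth


def split_two_sample(
    cohort: CohortData,
    outcome: np.ndarray,
    seed: int = 0,
    truth: Optional[SimulationTruth] = None,
):
    """Disjoint even split into an exposure cohort and an outcome cohort.

    The exposure cohort keeps risk factors, genotypes and covariates; the
    outcome cohort keeps genotypes, covariates and the outcome vector. With
    odd N the exposure side receives the extra individual. When ``truth`` is
    given, per-row ground truth is returned restricted to each side.
    """
    n = cohort.n_samples
    if n < 4:
        raise ValueError("need at least 4 individuals to split")
    rng = stream_rng(seed, "two-sample-split")
    perm = rng.permutation(n)
    n_exp = -(-n // 2)
    rows_exp = np.sort(perm[:n_exp])
    rows_out = np.sort(perm[n_exp:])
    exposure = cohort.subset_samples(rows_exp)
    outcome_cohort = cohort.subset_samples(rows_out)
    result = (exposure, (outcome_cohort, np.asarray(outcome)[rows_out]))
    if truth is None:
        return result
    return result + ((rows_exp, rows_out),)
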