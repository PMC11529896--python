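"""Association scans, instrument selection and summary-statistic harmonization.

Marginal covariate-adjusted linear-regression GWAS (via Frisch-Waugh
residualization), the rank-inverse-normal phenotype transform, min-P
multivariate clumping for selecting approximately independent instruments,
and allele harmonization of external outcome summary statistics against the
exposure cohort's variant metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .simulate import CohortData, GenotypeMatrix, VariantMeta

logger = logging.getLogger(__name__)

__all__ = [
    "ASSOC_COLUMNS",
    "SUMMARY_COLUMNS",
    "InstrumentSet",
    "RankInverseNormal",
    "rank_inverse_normal",
    "marginal_assoc",
    "batch_marginal_assoc",
    "min_p_across_factors",
    "clump",
    "outcome_summary_from_cohort",
    "harmonize",
]

#: schema of an association scan table
ASSOC_COLUMNS = ["variant_id", "beta", "se", "pvalue"]
#: schema of an outcome summary-statistics table
SUMMARY_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue"]


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Rank-inverse Gaussian transform with Blom offsets.

    Maps average ranks r to standard-normal quantiles at (r - 3/8)/(N + 1/4).
    Rejects constant input (no ordering to preserve).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-d vector of length >= 2")
    if np.ptp(v) == 0.0:
        raise ValueError("constant input has no rank ordering")
    r = rankdata(v, method="average")
    return ndtri((r - 0.375) / (v.size + 0.25))


class RankInverseNormal:
    """Fitted rank-inverse-normal transform reusable on new observations.

    Stores the sorted training values and their normal scores; new values are
    mapped by monotone interpolation between training quantiles (clamped at
    the extremes), so scoring is deterministic and order-preserving.
    """

    def __init__(self, values: np.ndarray):
        v = np.asarray(values, dtype=float)
        scores = rank_inverse_normal(v)
        order = np.argsort(v, kind="stable")
        self.train_sorted = v[order]
        self.score_sorted = scores[order]

    def __call__(self, new_values: np.ndarray) -> np.ndarray:
        x = np.asarray(new_values, dtype=float)
        return np.interp(x, self.train_sorted, self.score_sorted)

    def to_dict(self) -> dict:
        return {
            "train_sorted": self.train_sorted.tolist(),
            "score_sorted": self.score_sorted.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RankInverseNormal":
        obj = cls.__new__(cls)
        obj.train_sorted = np.asarray(d["train_sorted"], dtype=float)
        obj.score_sorted = np.asarray(d["score_sorted"], dtype=float)
        return obj


def _residualizer(F: np.ndarray):
    """Return a function projecting vectors/matrices off the column span of F."""
    F = np.asarray(F, dtype=float)
    q, _ = np.linalg.qr(F)

    def resid(v: np.ndarray) -> np.ndarray:
        return v - q @ (q.T @ v)

    return resid, F.shape[1]


def marginal_assoc(y: np.ndarray, G: GenotypeMatrix, F: np.ndarray) -> pd.DataFrame:
    """Per-variant marginal linear association of y on dosage, adjusting for F.

    For each variant the reported beta/se equal the genotype coefficient of
    the joint OLS fit y ~ dosage + F, computed by residualizing both sides on
    F (Frisch-Waugh). P-values use the two-sided normal approximation.
    Variants whose residualized dosage has zero variance get beta = NaN and
    are excluded downstream.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    resid, c = _residualizer(F)
    if n <= c + 1:
        raise ValueError("too few samples for covariate-adjusted regression")
    if np.ptp(y) == 0.0:
        return pd.DataFrame(
            {
                "variant_id": G.variant_ids,
                "beta": 0.0,
                "se": 0.0,
                "pvalue": 1.0,
            }
        )
    gt = resid(G.dosages)
    yt = resid(y)
    gg = np.einsum("ij,ij->j", gt, gt)
    gy = gt.T @ yt
    yy = float(yt @ yt)
    dof = n - c - 1

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(gg > 0, gy / np.where(gg > 0, gg, 1.0), np.nan)
        ssr = np.maximum(yy - beta**2 * gg, 0.0)
        sigma2 = ssr / dof
        se = np.sqrt(np.where(gg > 0, sigma2 / np.where(gg > 0, gg, 1.0), np.nan))
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pvalue = 2.0 * ndtr(-np.abs(z))
    # constant phenotype: define beta 0, p 1
    if yy == 0.0:
        beta = np.where(np.isnan(beta), np.nan, 0.0)
        pvalue = np.where(np.isnan(beta), np.nan, 1.0)
        se = np.where(np.isnan(se), np.nan, 0.0)
    pvalue = np.clip(pvalue, np.finfo(float).tiny, 1.0)
    if np.isnan(beta).any():
        bad = [G.variants[j].variant_id for j in np.flatnonzero(np.isnan(beta))]
        warnings.warn(f"{len(bad)} variant(s) with degenerate residualized dosage: {bad[:5]}")
    return pd.DataFrame(
        {"variant_id": G.variant_ids, "beta": beta, "se": se, "pvalue": pvalue}
    )


def batch_marginal_assoc(Y: np.ndarray, G: GenotypeMatrix, F: np.ndarray) -> list[pd.DataFrame]:
    """Marginal association scans for several phenotypes at once.

    Equivalent to calling :func:`marginal_assoc` per column of Y but
    residualizes the genotype matrix only once.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = Y.shape
    resid, c = _residualizer(F)
    if n <= c + 1:
        raise ValueError("too few samples for covariate-adjusted regression")
    gt = resid(G.dosages)
    yt = resid(Y)
    gg = np.einsum("ij,ij->j", gt, gt)
    yy = np.einsum("ik,ik->k", yt, yt)
    dof = n - c - 1
    scans = []
    with np.errstate(divide="ignore", invalid="ignore"):
        B = gt.T @ yt / np.where(gg > 0, gg, 1.0)[:, None]
        B[gg <= 0] = np.nan
        for j in range(k):
            beta = B[:, j]
            ssr = np.maximum(yy[j] - beta**2 * gg, 0.0)
            se = np.sqrt(ssr / dof / np.where(gg > 0, gg, 1.0))
            se[gg <= 0] = np.nan
            z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
            pvalue = np.clip(2.0 * ndtr(-np.abs(z)), np.finfo(float).tiny, 1.0)
            scans.append(
                pd.DataFrame(
                    {"variant_id": G.variant_ids, "beta": beta, "se": se, "pvalue": pvalue}
                )
            )
    return scans


def min_p_across_factors(scans: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-variant minimum p-value across factor scans, with the argmin factor."""
    if not scans:
        raise ValueError("need at least one scan")
    ids = list(scans[0]["variant_id"])
    for s in scans[1:]:
        if list(s["variant_id"]) != ids:
            raise ValueError("scans cover different variant lists")
    pmat = np.column_stack([s["pvalue"].to_numpy() for s in scans])
    pmat = np.where(np.isnan(pmat), np.inf, pmat)
    which = pmat.argmin(axis=1)
    minp = pmat[np.arange(len(ids)), which]
    return pd.DataFrame(
        {"variant_id": ids, "min_pvalue": minp, "argmin_factor": which}
    )


@dataclass
class InstrumentSet:
    """Clumped instrument list in selection order, with selection parameters."""

    variant_ids: list[str]
    min_pvalues: list[float]
    p_thresh: float = 5e-8
    r2_cutoff: float = 0.05
    window_kb: float = 5000.0
    removed: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variant_ids)


def clump(
    min_p: pd.DataFrame,
    G: GenotypeMatrix,
    p_thresh: float = 5e-8,
    r2_cutoff: float = 0.05,
    window_kb: float = 5000.0,
) -> InstrumentSet:
    """Greedy min-P clumping with an r^2 cutoff inside a distance window.

    Repeatedly selects the remaining variant with the smallest min-P below
    ``p_thresh`` as an index variant and removes unselected variants on the
    same chromosome within ``window_kb`` whose dosage r^2 with it exceeds
    ``r2_cutoff``. Ties in min-P break by (chromosome, position). r^2 is the
    squared Pearson correlation of dosage columns in the given cohort.
    """
    ids = list(min_p["variant_id"])
    index = {v.variant_id: j for j, v in enumerate(G.variants)}
    missing = [i for i in ids if i not in index]
    if missing:
        raise ValueError(f"variants absent from genotype matrix: {missing[:5]}")
    cols = np.array([index[i] for i in ids])
    chrom = np.array([G.variants[j].chromosome for j in cols])
    pos = np.array([G.variants[j].position for j in cols])
    pvals = min_p["min_pvalue"].to_numpy(dtype=float)

    order = sorted(
        range(len(ids)), key=lambda i: (pvals[i], chrom[i], pos[i])
    )
    centered = G.dosages[:, cols] - G.dosages[:, cols].mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", centered, centered))

    alive = pvals < p_thresh
    selected: list[int] = []
    removed: dict[str, str] = {}
    window_bp = window_kb * 1000.0
    for i in order:
        if not alive[i]:
            continue
        alive[i] = False
        selected.append(i)
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        if near.any() and norms[i] > 0:
            j = np.flatnonzero(near)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (centered[:, j].T @ centered[:, i]) / (norms[j] * norms[i])
            r2 = np.where(np.isfinite(r), r**2, 0.0)
            for jj, rr in zip(j[r2 > r2_cutoff], r2[r2 > r2_cutoff]):
                alive[jj] = False
                removed[ids[jj]] = f"r2={rr:.3f} with index {ids[i]}"
    return InstrumentSet(
        variant_ids=[ids[i] for i in selected],
        min_pvalues=[float(pvals[i]) for i in selected],
        p_thresh=p_thresh,
        r2_cutoff=r2_cutoff,
        window_kb=window_kb,
        removed=removed,
    )


def outcome_summary_from_cohort(
    outcome: np.ndarray, G: GenotypeMatrix, F: np.ndarray
) -> pd.DataFrame:
    """Outcome GWAS on the outcome cohort, in external summary-stats form.

    Stands in for downloading disease GWAS summary statistics: per-variant
    marginal effect, standard error and p-value, with allele metadata.
    """
    assoc = marginal_assoc(outcome, G, F)
    assoc.insert(1, "effect_allele", [v.effect_allele for v in G.variants])
    assoc.insert(2, "other_allele", [v.other_allele for v in G.variants])
    return assoc


def harmonize(
    exposure_variants: Sequence[VariantMeta],
    outcome_stats: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align outcome summary statistics to the exposure variants' alleles.

    Variants are matched by id; palindromic (A/T, C/G) variants are dropped;
    swapped effect/other alleles flip the sign of the outcome beta; any other
    allele combination is dropped as a mismatch. Returns the aligned table in
    exposure order and a per-variant drop log.
    """
    stats = outcome_stats.set_index("variant_id")
    rows, drops = [], []
    for v in exposure_variants:
        if v.variant_id not in stats.index:
            drops.append((v.variant_id, "absent from outcome stats"))
            continue
        if v.is_palindromic:
            drops.append((v.variant_id, "palindromic"))
            continue
        rec = stats.loc[v.variant_id]
        ea, oa = str(rec["effect_allele"]), str(rec["other_allele"])
        if (ea, oa) == (v.effect_allele, v.other_allele):
            flip = 1.0
        elif (ea, oa) == (v.other_allele, v.effect_allele):
            flip = -1.0
        else:
            drops.append((v.variant_id, f"allele mismatch {ea}/{oa}"))
            continue
        rows.append(
            {
                "variant_id": v.variant_id,
                "effect_allele": v.effect_allele,
                "other_allele": v.other_allele,
                "beta": flip * float(rec["beta"]),
                "se": float(rec["se"]),
                "pvalue": float(rec["pvalue"]),
            }
        )
    log = pd.DataFrame(drops, columns=["variant_id", "reason"])
    if len(log):
        logger.info("harmonize dropped %d variants", len(log))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS), log
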