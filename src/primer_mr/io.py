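"""Tab-separated readers and writers for cohorts, summary statistics and scores.

All files are TSV with a header row. A cohort directory holds
``genotypes.tsv`` (sample_id + one dosage column per variant),
``phenotypes.tsv`` (sample_id, factor columns, optionally ``outcome``),
``covariates.tsv`` and ``variants.tsv`` (variant metadata). Readers validate
ids and ranges and name the offending file and id in error messages;
summary-stats headers are matched case-insensitively and extra columns are
tolerated.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .simulate import CohortData, GenotypeMatrix, VariantMeta

logger = logging.getLogger(__name__)

__all__ = [
    "write_cohort",
    "read_cohort",
    "read_summary_stats",
    "write_summary_stats",
    "write_scores",
]

_REQUIRED_SUMMARY = ["variant_id", "effect_allele", "other_allele", "beta", "se"]


def write_cohort(
    cohort: CohortData, outdir, outcome: Optional[np.ndarray] = None
) -> Path:
    """Write a cohort directory of four TSVs; returns the directory path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    G = cohort.genotypes
    ids = G.sample_ids

    geno = pd.DataFrame(G.dosages, columns=G.variant_ids)
    geno.insert(0, "sample_id", ids)
    geno.to_csv(outdir / "genotypes.tsv", sep="\t", index=False, float_format="%.6g")

    pheno = pd.DataFrame(cohort.risk_factors, columns=cohort.factor_names)
    pheno.insert(0, "sample_id", ids)
    if outcome is not None:
        pheno["outcome"] = np.asarray(outcome, dtype=float)
    pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False, float_format="%.10g")

    cov = pd.DataFrame(
        cohort.covariates,
        columns=[f"covar_{j}" for j in range(cohort.covariates.shape[1])],
    )
    cov.insert(0, "sample_id", ids)
    cov.to_csv(outdir / "covariates.tsv", sep="\t", index=False, float_format="%.10g")

    var = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in G.variants],
            "chr": [v.chromosome for v in G.variants],
            "pos": [v.position for v in G.variants],
            "effect_allele": [v.effect_allele for v in G.variants],
            "other_allele": [v.other_allele for v in G.variants],
            "maf": [v.maf for v in G.variants],
        }
    )
    var.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    return outdir


def read_cohort(indir) -> tuple[CohortData, Optional[np.ndarray]]:
    """Read a cohort directory; returns (cohort, outcome-or-None)."""
    indir = Path(indir)
    for name in ("genotypes.tsv", "phenotypes.tsv", "covariates.tsv", "variants.tsv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing {name} in {indir}")
    geno = pd.read_csv(indir / "genotypes.tsv", sep="\t")
    pheno = pd.read_csv(indir / "phenotypes.tsv", sep="\t")
    cov = pd.read_csv(indir / "covariates.tsv", sep="\t")
    var = pd.read_csv(indir / "variants.tsv", sep="\t")

    ids = list(geno["sample_id"].astype(str))
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise ValueError(f"genotypes.tsv: duplicate sample id {dup!r}")
    for name, df in (("phenotypes.tsv", pheno), ("covariates.tsv", cov)):
        got = list(df["sample_id"].astype(str))
        missing = set(ids) - set(got)
        extra = set(got) - set(ids)
        if missing or extra:
            off = sorted(missing or extra)[0]
            raise ValueError(f"{name}: sample id mismatch with genotypes.tsv ({off!r})")
        df.set_index("sample_id", inplace=True)
    pheno = pheno.loc[ids]
    cov = cov.loc[ids]

    variants = [
        VariantMeta(
            variant_id=str(r.variant_id),
            chromosome=int(r.chr),
            position=int(r.pos),
            effect_allele=str(r.effect_allele),
            other_allele=str(r.other_allele),
            maf=float(r.maf),
        )
        for r in var.itertuples()
    ]
    vids = [v.variant_id for v in variants]
    missing_cols = [v for v in vids if v not in geno.columns]
    if missing_cols:
        raise ValueError(f"genotypes.tsv: missing dosage column {missing_cols[0]!r}")
    dosages = geno[vids].to_numpy(dtype=float)
    if dosages.min() < 0 or dosages.max() > 2:
        j = np.argwhere((dosages < 0) | (dosages > 2))[0]
        raise ValueError(
            f"genotypes.tsv: dosage outside [0, 2] for sample {ids[j[0]]!r}, "
            f"variant {vids[j[1]]!r}"
        )

    factor_names = [c for c in pheno.columns if c != "outcome"]
    outcome = pheno["outcome"].to_numpy(dtype=float) if "outcome" in pheno else None
    cohort = CohortData(
        genotypes=GenotypeMatrix(dosages=dosages, variants=variants, sample_ids=ids),
        risk_factors=pheno[factor_names].to_numpy(dtype=float),
        covariates=cov.to_numpy(dtype=float),
        factor_names=factor_names,
    )
    return cohort, outcome


def read_summary_stats(path) -> pd.DataFrame:
    """Read an outcome summary-statistics TSV.

    Headers are case-insensitive and extra columns are tolerated. Rows with
    non-positive standard errors or non-finite effects are dropped with a
    logged count; a missing p-value column is recomputed from beta/se under
    the two-sided normal approximation.
    """
    df = pd.read_csv(path, sep="\t")
    lower = {c.lower(): c for c in df.columns}
    for col in _REQUIRED_SUMMARY:
        if col not in lower:
            raise ValueError(f"{path}: missing required column {col!r}")
    out = pd.DataFrame(
        {col: df[lower[col]] for col in _REQUIRED_SUMMARY}
    )
    out["beta"] = out["beta"].astype(float)
    out["se"] = out["se"].astype(float)
    if "pvalue" in lower:
        out["pvalue"] = df[lower["pvalue"]].astype(float)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = out["beta"] / out["se"]
        out["pvalue"] = 2.0 * ndtr(-np.abs(z))
    bad = ~np.isfinite(out["beta"]) | ~(out["se"] > 0)
    if bad.any():
        logger.info("dropping %d invalid summary rows from %s", int(bad.sum()), path)
        out = out.loc[~bad].reset_index(drop=True)
    if out["variant_id"].duplicated().any():
        dup = out.loc[out["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"{path}: duplicate variant id {dup!r}")
    return out


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_scores(sample_ids, scores: np.ndarray, path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "score": np.asarray(scores, float)}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
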