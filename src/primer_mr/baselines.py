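"""Comparison risk predictors.

* UVMR-based: per-factor univariate IVW causal effects, gated on instrument
  count (>= 5 genome-wide significant) and Bonferroni-corrected significance.
* MVMR-based: joint weighted least squares of outcome effects on the factor
  effect-size matrix B_e, with the same inverse-variance weights as IVW.
* PRiMeR-LIN: the ELBO machinery of :class:`~primer_mr.model.PrimerModel`
  with identity warping (``linear=True``).
* LRM: a supervised reference sharing the ELU risk-function architecture,
  trained directly on individual-level labels (MSE for continuous risk,
  cross-entropy through a logistic link for binary onset) with inner 5-fold
  cross-validation over learning rate and weight decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .core import (
    Adam,
    RiskFunctionParams,
    clip_global_norm,
    ivw_closed_form,
    risk_function_backward,
    risk_function_forward,
)
from .gwas import InstrumentSet, RankInverseNormal

__all__ = [
    "LinearPredictorWeights",
    "fit_uvmr",
    "fit_mvmr",
    "LinearScorer",
    "LrmModel",
    "LrmResults",
]


@dataclass
class LinearPredictorWeights:
    """Per-factor weights a_k of a linear risk predictor f(X) = X a."""

    a: np.ndarray
    provenance: str
    n_instruments: list[int] = field(default_factory=list)
    pvalues: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if not np.isfinite(self.a).all():
            raise ValueError("non-finite predictor weights")


def fit_uvmr(
    per_factor_scans: Sequence[pd.DataFrame],
    per_factor_instruments: Sequence[InstrumentSet],
    outcome_stats: pd.DataFrame,
    min_instruments: int = 5,
    alpha_level: float = 0.05,
) -> LinearPredictorWeights:
    """Univariate-MR weights with instrument-count and significance gates.

    a_k is the IVW slope of factor k's own instruments, set to zero unless
    the factor has at least ``min_instruments`` instruments present in the
    harmonized outcome statistics and its slope survives Bonferroni
    correction across all K factors at ``alpha_level``.
    """
    k = len(per_factor_scans)
    if len(per_factor_instruments) != k:
        raise ValueError("scan and instrument lists differ in length")
    out = outcome_stats.set_index("variant_id")
    a = np.zeros(k)
    counts, pvals = [], []
    for j in range(k):
        ids = [i for i in per_factor_instruments[j].variant_ids if i in out.index]
        counts.append(len(ids))
        if len(ids) < min_instruments:
            pvals.append(1.0)
            continue
        scan = per_factor_scans[j].set_index("variant_id").loc[ids]
        beta_e = scan["beta"].to_numpy(dtype=float)
        beta_o = out.loc[ids, "beta"].to_numpy(dtype=float)
        se_o = out.loc[ids, "se"].to_numpy(dtype=float)
        try:
            alpha_hat, se = ivw_closed_form(beta_e, beta_o, se_o)
        except ValueError:
            pvals.append(1.0)
            continue
        p = 2.0 * float(ndtr(-abs(alpha_hat / se)))
        pvals.append(p)
        if p < alpha_level / k:
            a[j] = alpha_hat
    return LinearPredictorWeights(
        a=a, provenance="uvmr", n_instruments=counts, pvalues=pvals
    )


def fit_mvmr(
    B_e: np.ndarray,
    outcome_stats: pd.DataFrame,
    cond_limit: float = 1e10,
) -> LinearPredictorWeights:
    """Multivariable-MR weights by inverse-variance weighted least squares.

    Solves a = argmin sum_s w_s (beta_o_s - B_e[s] a)^2 with w = 1/se^2 and
    no intercept. Rejects rank-deficient weighted designs with a
    condition-number diagnostic.
    """
    B_e = np.asarray(B_e, dtype=float)
    beta_o = outcome_stats["beta"].to_numpy(dtype=float)
    se_o = outcome_stats["se"].to_numpy(dtype=float)
    if B_e.shape[0] != beta_o.size:
        raise ValueError("B_e rows must match outcome statistics")
    if B_e.shape[0] < B_e.shape[1]:
        raise ValueError("need at least as many instruments as factors")
    sw = 1.0 / se_o
    design = B_e * sw[:, None]
    target = beta_o * sw
    cond = np.linalg.cond(design)
    if not np.isfinite(cond) or cond > cond_limit:
        raise ValueError(f"weighted design rank-deficient (condition number {cond:.3g})")
    a, *_ = np.linalg.lstsq(design, target, rcond=None)
    return LinearPredictorWeights(a=a, provenance="mvmr")


class LinearScorer:
    """Scores individuals with fixed linear weights after rank normalization."""

    def __init__(
        self,
        weights: LinearPredictorWeights,
        transforms: Optional[list[RankInverseNormal]] = None,
    ):
        self.weights = weights
        self.transforms = transforms

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X = np.asarray(X_new, dtype=float)
        if self.transforms is not None:
            X = np.column_stack([t(X[:, j]) for j, t in enumerate(self.transforms)])
        return X @ self.weights.a


class LrmModel:
    """Supervised reference model sharing the ELU risk-function form.

    Fits f_phi by full-batch Adam on the mean squared error (continuous
    labels) or binary cross-entropy through a logistic link (binary labels),
    with hyperparameters chosen by inner 5-fold cross-validation.
    """

    def __init__(
        self,
        X: np.ndarray,
        labels: np.ndarray,
        binary: bool = False,
        normalize: bool = True,
    ):
        X = np.asarray(X, dtype=float)
        y = np.asarray(labels, dtype=float)
        if X.shape[0] != y.size:
            raise ValueError("label length does not match X rows")
        if binary:
            classes = np.unique(y)
            if classes.size < 2:
                raise ValueError("binary labels must contain both classes")
        self.binary = binary
        self.k = X.shape[1]
        if normalize:
            self.transforms = [RankInverseNormal(X[:, j]) for j in range(self.k)]
            self.X = np.column_stack([t(X[:, j]) for j, t in enumerate(self.transforms)])
        else:
            self.transforms = None
            self.X = X
        self.y = y

    def _train(self, X, y, lr, weight_decay, epochs, seed):
        rng = np.random.default_rng(seed)
        k = self.k
        theta = np.concatenate(
            [rng.normal(0, 0.1, k), np.ones(k) + rng.normal(0, 0.1, k), np.zeros(k)]
        )
        opt = Adam(lr=lr)
        n = y.size
        for _ in range(epochs):
            params = RiskFunctionParams.unpack(theta, k)
            e, cache = risk_function_forward(X, params, with_cache=True)
            if self.binary:
                p = expit(e)
                dL_de = (p - y) / n
            else:
                dL_de = 2.0 * (e - y) / n
            grad = risk_function_backward(dL_de, cache, params) + weight_decay * theta
            (grad,) = clip_global_norm([grad], 10.0)
            theta = opt.step(theta, grad)
        return theta

    def _score(self, theta, X, y):
        params = RiskFunctionParams.unpack(theta, self.k)
        e = risk_function_forward(X, params)
        if self.binary:
            p = np.clip(expit(e), 1e-12, 1 - 1e-12)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))
        return float(np.mean((e - y) ** 2))

    def fit(
        self,
        cv_grid: Optional[dict] = None,
        epochs: int = 500,
        cv_epochs: int = 200,
        n_folds: int = 5,
        seed: int = 0,
    ) -> "LrmResults":
        grid = cv_grid or {"lr": [0.01, 0.001], "weight_decay": [0.0, 1e-4, 1e-2]}
        n = self.y.size
        rng = np.random.default_rng(seed)
        folds = rng.permutation(n) % n_folds
        best, best_loss = None, np.inf
        for lr in grid["lr"]:
            for wd in grid["weight_decay"]:
                losses = []
                for f in range(n_folds):
                    tr, va = folds != f, folds == f
                    theta = self._train(
                        self.X[tr], self.y[tr], lr, wd, cv_epochs, seed + f
                    )
                    losses.append(self._score(theta, self.X[va], self.y[va]))
                mean_loss = float(np.mean(losses))
                if mean_loss < best_loss:
                    best_loss, best = mean_loss, (lr, wd)
        lr, wd = best
        theta = self._train(self.X, self.y, lr, wd, epochs, seed)
        return LrmResults(
            model=self, theta=theta, lr=lr, weight_decay=wd, cv_loss=best_loss
        )


@dataclass
class LrmResults:
    """Fitted supervised reference predictor."""

    model: LrmModel
    theta: np.ndarray
    lr: float
    weight_decay: float
    cv_loss: float

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X = np.asarray(X_new, dtype=float)
        if self.model.transforms is not None:
            X = np.column_stack(
                [t(X[:, j]) for j, t in enumerate(self.model.transforms)]
            )
        params = RiskFunctionParams.unpack(self.theta, self.model.k)
        e = risk_function_forward(X, params)
        return expit(e) if self.model.binary else e
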