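"""The IVW-aligned risk-predictor model and its fitted results object.

``PrimerModel`` learns a nonlinear aggregate risk function
f_phi(X) = sum_k a_k ELU(b_k x_k + c_k) from individual-level exposure-cohort
data by aligning the predictor's marginal genetic effects with external
outcome GWAS effects through the IVW regression likelihood. Inference is
Bayesian: independent Gaussian priors on phi, a diagonal-Gaussian variational
posterior optimized by stochastic gradient ascent on the ELBO (Adam,
reparametrization trick), with the regression slope alpha and variance scale
sigma^2 treated as point parameters (sigma^2 on the log scale). Risk scores
for new individuals are posterior-mean predictions.

``linear=True`` gives the linear variant of the same machinery (identity
warping, parameters reduced to the factor weights a), which recovers
multivariable MR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    Adam,
    GeneticEffectsOperator,
    RiskFunctionParams,
    clip_global_norm,
    ivw_closed_form,
    ivw_loss_grads,
    risk_function_backward,
    risk_function_forward,
)
from .gwas import RankInverseNormal, harmonize
from .simulate import CohortData

__all__ = ["PrimerModel", "PrimerResults", "elbo", "FitConfig"]

_PREDICT_SEED = 20_240_101  # fixed internal seed for posterior-draw scoring


@dataclass(frozen=True)
class FitConfig:
    """Training hyperparameters (defaults follow the published recipe)."""

    lr: float = 0.01
    epochs: int = 1000
    clip_norm: float = 1.0
    mc_samples: int = 8
    prior_scale: float = 1.0
    seed: int = 0


def _kl_diag_gaussian(mu: np.ndarray, log_sd: np.ndarray, tau: float) -> float:
    """KL( N(mu, sd^2) || N(0, tau^2) ) summed over coordinates."""
    sd2 = np.exp(2.0 * log_sd)
    return float(
        np.sum(np.log(tau) - log_sd + (sd2 + mu**2) / (2.0 * tau**2) - 0.5)
    )


def elbo(
    mu: np.ndarray,
    log_sd: np.ndarray,
    alpha: float,
    sigma2: float,
    X: np.ndarray,
    op: GeneticEffectsOperator,
    beta_o: np.ndarray,
    se_o: np.ndarray,
    prior_scale: float = 1.0,
    mc_samples: int = 8,
    seed: int = 0,
    linear: bool = False,
) -> float:
    """Monte-Carlo estimate of the evidence lower bound.

    ELBO = E_q[-L_IVW(phi, alpha, sigma2)] - KL(q(phi) || p(phi)), with the
    expectation over the reparametrized posterior phi = mu + sd * eps.
    """
    rng = np.random.default_rng(seed)
    k = X.shape[1]
    sd = np.exp(log_sd)
    total = 0.0
    for _ in range(mc_samples):
        phi = mu + sd * rng.standard_normal(mu.size)
        params = RiskFunctionParams.unpack(phi, k, linear=linear)
        e = risk_function_forward(X, params)
        loss, *_ = ivw_loss_grads(op.beta(e), alpha, sigma2, beta_o, se_o)
        total += loss
    return -total / mc_samples - _kl_diag_gaussian(mu, log_sd, prior_scale)


class PrimerModel:
    """Risk-predictor model built from an exposure cohort and outcome GWAS.

    Parameters
    ----------
    X : (N, K) array
        Raw risk-factor matrix of the exposure cohort. Each column is
        rank-inverse-normalized internally; the fitted transforms are stored
        so new individuals are mapped through the training quantiles.
    dosages : (N, S) array
        Additive genotype dosages of the instrument variants, column-aligned
        with ``outcome_stats``.
    covariates : (N, C) array
        Covariate matrix including an intercept column.
    outcome_stats : DataFrame
        Harmonized outcome summary statistics (columns ``variant_id``,
        ``beta``, ``se``), row-aligned with the dosage columns.
    linear : bool
        Fit the linear variant (identity warping) instead of the ELU form.
    """

    def __init__(
        self,
        X: np.ndarray,
        dosages: np.ndarray,
        covariates: np.ndarray,
        outcome_stats: pd.DataFrame,
        factor_names: Optional[list[str]] = None,
        linear: bool = False,
        normalize: bool = True,
    ):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.k = X.shape[1]
        self.linear = linear
        self.factor_names = factor_names or [f"factor_{j + 1}" for j in range(self.k)]
        if normalize:
            self.transforms = [RankInverseNormal(X[:, j]) for j in range(self.k)]
            self.X = np.column_stack([t(X[:, j]) for j, t in enumerate(self.transforms)])
        else:
            self.transforms = None
            self.X = X
        ids = list(outcome_stats["variant_id"])
        if len(ids) != np.asarray(dosages).shape[1]:
            raise ValueError("outcome_stats rows must align with dosage columns")
        self.op = GeneticEffectsOperator(dosages, covariates, variant_ids=ids)
        stats = outcome_stats.iloc[self.op.kept]
        se = stats["se"].to_numpy(dtype=float)
        if np.any(se <= 0):
            raise ValueError("outcome standard errors must be positive")
        self.beta_o = stats["beta"].to_numpy(dtype=float)
        self.se_o = se
        self.variant_ids = list(stats["variant_id"])

    @classmethod
    def from_cohort(
        cls,
        cohort: CohortData,
        outcome_stats: pd.DataFrame,
        instruments=None,
        linear: bool = False,
    ) -> "PrimerModel":
        """Build from a cohort, subsetting to instruments and harmonizing alleles."""
        G = cohort.genotypes
        if instruments is not None:
            ids = instruments if isinstance(instruments, list) else instruments.variant_ids
            G = G.subset_variants(ids)
        aligned, _ = harmonize(G.variants, outcome_stats)
        G = G.subset_variants(list(aligned["variant_id"]))
        return cls(
            X=cohort.risk_factors,
            dosages=G.dosages,
            covariates=cohort.covariates,
            outcome_stats=aligned,
            factor_names=list(cohort.factor_names),
            linear=linear,
        )

    @property
    def n_params(self) -> int:
        return self.k if self.linear else 3 * self.k

    def _init_state(self, config: FitConfig):
        rng = np.random.default_rng(config.seed)
        k, p = self.k, self.n_params
        mu = np.zeros(p)
        mu[:k] = rng.normal(0.0, 0.1, size=k)  # a
        if not self.linear:
            mu[k : 2 * k] = rng.normal(0.0, 0.1, size=k)  # b
        log_sd = np.full(p, np.log(0.1))
        params0 = RiskFunctionParams.unpack(mu, k, linear=self.linear)
        beta_e0 = self.op.beta(risk_function_forward(self.X, params0))
        try:
            a0, _ = ivw_closed_form(beta_e0, self.beta_o, self.se_o)
            alpha = abs(a0) if np.isfinite(a0) and abs(a0) > 0 else 1.0
        except ValueError:
            alpha = 1.0
        return mu, log_sd, float(alpha), 0.0, rng  # log_sigma2 = 0 -> sigma2 = 1

    def fit(self, config: Optional[FitConfig] = None, **overrides) -> "PrimerResults":
        """Maximize the ELBO by Adam with gradient clipping.

        Draws ``mc_samples`` reparametrized posterior samples per epoch, takes
        one full-batch gradient step on (mu, log_sd, alpha, log sigma^2), and
        logs the negative ELBO per epoch. Aborts with a diagnostic on a
        non-finite objective.
        """
        cfg = config or FitConfig(**overrides)
        if overrides and config is not None:
            raise ValueError("pass either a FitConfig or keyword overrides, not both")
        k, p = self.k, self.n_params
        mu, log_sd, alpha, log_s2, rng = self._init_state(cfg)
        tau = cfg.prior_scale
        opt = Adam(lr=cfg.lr)
        theta = np.concatenate([mu, log_sd, [alpha, log_s2]])
        history = []
        X, op, beta_o, se_o = self.X, self.op, self.beta_o, self.se_o
        m = cfg.mc_samples
        for epoch in range(cfg.epochs):
            mu, log_sd = theta[:p], theta[p : 2 * p]
            alpha, log_s2 = theta[2 * p], theta[2 * p + 1]
            sd = np.exp(log_sd)
            sigma2 = float(np.exp(log_s2))
            eps = rng.standard_normal((m, p))
            g_mu = np.zeros(p)
            g_lsd = np.zeros(p)
            g_alpha = 0.0
            g_ls2 = 0.0
            loss_sum = 0.0
            for i in range(m):
                phi = mu + sd * eps[i]
                params = RiskFunctionParams.unpack(phi, k, linear=self.linear)
                e, cache = risk_function_forward(X, params, with_cache=True)
                loss, d_be, d_a, d_ls2 = ivw_loss_grads(
                    op.beta(e), alpha, sigma2, beta_o, se_o
                )
                g_phi = risk_function_backward(op.backprop(d_be), cache, params)
                g_mu += g_phi / m
                g_lsd += g_phi * eps[i] * sd / m
                g_alpha += d_a / m
                g_ls2 += d_ls2 / m
                loss_sum += loss / m
            # KL(q || prior) gradients
            g_mu += mu / tau**2
            g_lsd += -1.0 + sd**2 / tau**2
            kl = _kl_diag_gaussian(mu, log_sd, tau)
            neg_elbo = loss_sum + kl
            if not np.isfinite(neg_elbo):
                raise RuntimeError(
                    f"non-finite objective at epoch {epoch}; "
                    f"last alpha={alpha:.4g}, sigma2={sigma2:.4g}"
                )
            history.append(neg_elbo)
            grads = clip_global_norm(
                [g_mu, g_lsd, np.array([g_alpha]), np.array([g_ls2])], cfg.clip_norm
            )
            grad = np.concatenate(grads)
            theta = opt.step(theta, grad)
        mu, log_sd = theta[:p], theta[p : 2 * p]
        return PrimerResults(
            model=self,
            posterior_mean=mu,
            posterior_log_sd=log_sd,
            alpha=float(theta[2 * p]),
            sigma2=float(np.exp(theta[2 * p + 1])),
            history=np.asarray(history),
            config=cfg,
        )


@dataclass
class PrimerResults:
    """Fitted variational posterior over phi plus IVW nuisance parameters."""

    model: PrimerModel
    posterior_mean: np.ndarray
    posterior_log_sd: np.ndarray
    alpha: float
    sigma2: float
    history: np.ndarray
    config: FitConfig
    _extra: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def linear(self) -> bool:
        return self.model.linear

    @property
    def final_loss(self) -> float:
        return float(self.history[-1]) if len(self.history) else float("nan")

    def params_at_mean(self) -> RiskFunctionParams:
        return RiskFunctionParams.unpack(self.posterior_mean, self.k, linear=self.linear)

    def _normalize(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim != 2 or X_new.shape[1] != self.k:
            raise ValueError(
                f"expected {self.k} factor columns, got {X_new.shape[1] if X_new.ndim == 2 else 'non-2d'}"
            )
        if self.model.transforms is None:
            return X_new
        return np.column_stack(
            [t(X_new[:, j]) for j, t in enumerate(self.model.transforms)]
        )

    def predict(self, X_new: np.ndarray, draws: int = 256) -> np.ndarray:
        """Posterior-mean risk score for new individuals.

        Averages the risk function over ``draws`` posterior samples drawn
        with a fixed internal seed, after mapping the new factor values
        through the stored training normalization.
        """
        Xn = self._normalize(X_new)
        rng = np.random.default_rng(_PREDICT_SEED)
        sd = np.exp(self.posterior_log_sd)
        scores = np.zeros(Xn.shape[0])
        for _ in range(draws):
            phi = self.posterior_mean + sd * rng.standard_normal(self.posterior_mean.size)
            params = RiskFunctionParams.unpack(phi, self.k, linear=self.linear)
            scores += risk_function_forward(Xn, params)
        return scores / draws

    def predict_at_mean(self, X_new: np.ndarray) -> np.ndarray:
        """Risk score at the posterior mean parameters (no posterior averaging)."""
        return risk_function_forward(self._normalize(X_new), self.params_at_mean())

    def summary(self) -> str:
        """Human-readable fit summary table."""
        p = self.params_at_mean()
        sd = np.exp(self.posterior_log_sd)
        lines = [
            "IVW-aligned risk predictor"
            + (" (linear)" if self.linear else " (ELU-warped)"),
            f"  factors: {self.k}   instruments: {len(self.model.variant_ids)}",
            f"  alpha = {self.alpha:.4f}   sigma2 = {self.sigma2:.4f}",
            f"  final negative ELBO = {self.final_loss:.4f} "
            f"({self.config.epochs} epochs, lr {self.config.lr})",
            "",
            f"  {'factor':<20}{'a (mean+/-sd)':<22}"
            + ("" if self.linear else f"{'b':<22}{'c':<22}"),
        ]
        for j, name in enumerate(self.model.factor_names):
            row = f"  {name:<20}{p.a[j]:>8.4f} +/- {sd[j]:<8.4f}"
            if not self.linear:
                row += (
                    f"{p.b[j]:>8.4f} +/- {sd[self.k + j]:<8.4f}"
                    f"{p.c[j]:>8.4f} +/- {sd[2 * self.k + j]:<8.4f}"
                )
            lines.append(row)
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "linear": self.linear,
            "k": self.k,
            "factor_names": self.model.factor_names,
            "posterior_mean": self.posterior_mean.tolist(),
            "posterior_log_sd": self.posterior_log_sd.tolist(),
            "alpha": self.alpha,
            "sigma2": self.sigma2,
            "config": {
                "lr": self.config.lr,
                "epochs": self.config.epochs,
                "clip_norm": self.config.clip_norm,
                "mc_samples": self.config.mc_samples,
                "prior_scale": self.config.prior_scale,
                "seed": self.config.seed,
            },
            "history": self.history.tolist(),
            "transforms": (
                [t.to_dict() for t in self.model.transforms]
                if self.model.transforms is not None
                else None
            ),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PrimerScorer":
        with open(path) as fh:
            return PrimerScorer(json.load(fh))


class PrimerScorer:
    """Deserialized predictor: scores new individuals without training state."""

    def __init__(self, d: dict):
        self.k = int(d["k"])
        self.linear = bool(d["linear"])
        self.factor_names = list(d["factor_names"])
        self.posterior_mean = np.asarray(d["posterior_mean"], dtype=float)
        self.posterior_log_sd = np.asarray(d["posterior_log_sd"], dtype=float)
        self.alpha = float(d["alpha"])
        self.sigma2 = float(d["sigma2"])
        self.transforms = (
            [RankInverseNormal.from_dict(t) for t in d["transforms"]]
            if d.get("transforms")
            else None
        )

    def predict(self, X_new: np.ndarray, draws: int = 256) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != self.k:
            raise ValueError(f"expected {self.k} factor columns")
        if self.transforms is not None:
            X_new = np.column_stack(
                [t(X_new[:, j]) for j, t in enumerate(self.transforms)]
            )
        rng = np.random.default_rng(_PREDICT_SEED)
        sd = np.exp(self.posterior_log_sd)
        scores = np.zeros(X_new.shape[0])
        for _ in range(draws):
            phi = self.posterior_mean + sd * rng.standard_normal(self.posterior_mean.size)
            params = RiskFunctionParams.unpack(phi, self.k, linear=self.linear)
            scores += risk_function_forward(X_new, params)
        return scores / draws
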