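"""Differentiable building blocks of the IVW-aligned risk predictor.

The learned predictor is e_i = sum_k a_k ELU(b_k x_ik + c_k). Its marginal
genetic effects beta_e(phi) are the covariate-adjusted per-variant regression
slopes of e on each dosage column; because residualization is a fixed linear
map, beta_e = A e for a precomputable matrix A, and gradients of the IVW
regression loss

    L(phi, alpha, sigma2) = -log N(beta_o | alpha * beta_e(phi),
                                   sigma2 * diag(s_o^2))

propagate to phi in closed form. Everything here is plain numpy with
hand-derived backward passes; a finite-difference check in the test suite
guards each gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "elu",
    "elu_grad",
    "risk_function_forward",
    "RiskFunctionParams",
    "GeneticEffectsOperator",
    "ivw_loss",
    "ivw_loss_grads",
    "ivw_closed_form",
    "Adam",
    "clip_global_norm",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def elu(z: np.ndarray) -> np.ndarray:
    """Exponential linear unit: z for z >= 0, exp(z) - 1 below."""
    return np.where(z >= 0, z, np.expm1(np.minimum(z, 0.0)))


def elu_grad(z: np.ndarray) -> np.ndarray:
    """d ELU / dz: 1 for z >= 0, exp(z) below."""
    return np.where(z >= 0, 1.0, np.exp(np.minimum(z, 0.0)))


@dataclass
class RiskFunctionParams:
    """Parameters phi of the additive ELU-warped risk function.

    ``a`` are outer factor weights, ``b`` inner scales and ``c`` inner
    offsets; a linear predictor fixes b = 1, c = 0 and learns only ``a``.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    linear: bool = False

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        if not (self.a.shape == self.b.shape == self.c.shape):
            raise ValueError("a, b, c must have equal length K")
        if not np.isfinite(self.a).all() or not np.isfinite(self.b).all() or not np.isfinite(self.c).all():
            raise ValueError("non-finite risk-function parameters")

    @property
    def k(self) -> int:
        return self.a.size

    def pack(self) -> np.ndarray:
        if self.linear:
            return self.a.copy()
        return np.concatenate([self.a, self.b, self.c])

    @classmethod
    def unpack(cls, vec: np.ndarray, k: int, linear: bool = False) -> "RiskFunctionParams":
        vec = np.asarray(vec, dtype=float)
        if linear:
            return cls(a=vec[:k], b=np.ones(k), c=np.zeros(k), linear=True)
        return cls(a=vec[:k], b=vec[k : 2 * k], c=vec[2 * k :], linear=False)


def risk_function_forward(
    X: np.ndarray, params: RiskFunctionParams, with_cache: bool = False
):
    """Evaluate e = sum_k a_k ELU(b_k X_k + c_k) row-wise.

    With ``with_cache`` the intermediates needed for the backward pass are
    returned alongside. For linear parameters the warping reduces to the
    identity, e = X a.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite risk factor values")
    if X.ndim != 2 or X.shape[1] != params.k:
        raise ValueError("X has wrong number of factor columns")
    if params.linear:
        e = X @ params.a
        return (e, {"X": X}) if with_cache else e
    Z = X * params.b + params.c
    H = elu(Z)
    e = H @ params.a
    if not with_cache:
        return e
    return e, {"X": X, "Z": Z, "H": H}


def risk_function_backward(
    dL_de: np.ndarray, cache: dict, params: RiskFunctionParams
) -> np.ndarray:
    """Backpropagate a gradient w.r.t. e to the packed parameter vector."""
    if params.linear:
        return cache["X"].T @ dL_de
    X, Z, H = cache["X"], cache["Z"], cache["H"]
    dH = elu_grad(Z)
    grad_a = H.T @ dL_de
    inner = dH * (dL_de[:, None] * params.a[None, :])
    grad_b = np.einsum("ik,ik->k", inner, X)
    grad_c = inner.sum(axis=0)
    return np.concatenate([grad_a, grad_b, grad_c])


class GeneticEffectsOperator:
    """Fixed linear map from a risk predictor e to its marginal genetic effects.

    beta_e[s] = (g~_s . e~) / (g~_s . g~_s) where g~, e~ are residuals after
    projection on the covariates F. Since the projector is symmetric and
    idempotent, beta_e = A e with A = D^-1 (M G)^T, precomputed once per
    cohort; the adjoint A^T carries loss gradients back to e. Variants whose
    residualized dosage has (near-)zero norm are excluded with a warning.
    """

    def __init__(self, dosages: np.ndarray, F: np.ndarray, variant_ids=None):
        import warnings

        G = np.asarray(dosages, dtype=float)
        F = np.asarray(F, dtype=float)
        q, _ = np.linalg.qr(F)
        gt = G - q @ (q.T @ G)
        norms2 = np.einsum("ij,ij->j", gt, gt)
        keep = norms2 > 1e-12 * G.shape[0]
        if not keep.all():
            bad = np.flatnonzero(~keep)
            names = [variant_ids[j] if variant_ids else str(j) for j in bad]
            warnings.warn(f"excluding {bad.size} degenerate variant(s): {names[:5]}")
        self.kept = np.flatnonzero(keep)
        self.variant_ids = (
            [variant_ids[j] for j in self.kept] if variant_ids is not None else None
        )
        # residualizing e is unnecessary: g~^T e = g~^T e~ exactly
        self.A = (gt[:, keep] / norms2[keep]).T

    @property
    def n_variants(self) -> int:
        return self.A.shape[0]

    def beta(self, e: np.ndarray) -> np.ndarray:
        return self.A @ e

    def backprop(self, dL_dbeta: np.ndarray) -> np.ndarray:
        return self.A.T @ dL_dbeta


def ivw_loss(
    beta_e: np.ndarray,
    alpha: float,
    sigma2: float,
    beta_o: np.ndarray,
    se_o: np.ndarray,
) -> float:
    """Negative log-likelihood of the IVW regression model.

    -log N(beta_o | alpha * beta_e, sigma2 * diag(se_o^2)), summed over
    variants. Requires sigma2 > 0 and all se_o > 0.
    """
    beta_e = np.asarray(beta_e, dtype=float)
    beta_o = np.asarray(beta_o, dtype=float)
    se_o = np.asarray(se_o, dtype=float)
    if np.any(se_o <= 0):
        raise ValueError("all outcome standard errors must be positive")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    var = sigma2 * se_o**2
    r = beta_o - alpha * beta_e
    return float(0.5 * np.sum(r**2 / var + np.log(var) + _LOG_2PI))


def ivw_loss_grads(
    beta_e: np.ndarray,
    alpha: float,
    sigma2: float,
    beta_o: np.ndarray,
    se_o: np.ndarray,
):
    """Value and analytic gradients of the IVW loss.

    Returns (loss, dL/dbeta_e, dL/dalpha, dL/dlog_sigma2); the variance scale
    is differentiated on the log scale, matching its parameterization during
    training.
    """
    var = sigma2 * se_o**2
    r = beta_o - alpha * beta_e
    loss = float(0.5 * np.sum(r**2 / var + np.log(var) + _LOG_2PI))
    d_beta_e = -alpha * r / var
    d_alpha = float(-np.sum(beta_e * r / var))
    d_log_sigma2 = float(-0.5 * np.sum(r**2 / var) + 0.5 * r.size)
    return loss, d_beta_e, d_alpha, d_log_sigma2


def ivw_closed_form(
    beta_e: np.ndarray, beta_o: np.ndarray, se_o: np.ndarray
) -> tuple[float, float]:
    """Closed-form IVW slope and its standard error.

    alpha_hat = sum(w beta_e beta_o) / sum(w beta_e^2), w = 1/se_o^2;
    SE = 1/sqrt(sum(w beta_e^2)).
    """
    beta_e = np.asarray(beta_e, dtype=float)
    beta_o = np.asarray(beta_o, dtype=float)
    se_o = np.asarray(se_o, dtype=float)
    if np.any(se_o <= 0):
        raise ValueError("all outcome standard errors must be positive")
    w = 1.0 / se_o**2
    denom = float(np.sum(w * beta_e**2))
    if denom == 0.0:
        raise ValueError("all exposure effects zero: slope undefined")
    alpha_hat = float(np.sum(w * beta_e * beta_o) / denom)
    return alpha_hat, float(1.0 / np.sqrt(denom))


def clip_global_norm(grads: list[np.ndarray], max_norm: float) -> list[np.ndarray]:
    """Rescale a gradient list so its joint L2 norm is at most max_norm."""
    total = np.sqrt(sum(float(np.sum(g**2)) for g in grads))
    if total > max_norm > 0:
        scale = max_norm / total
        return [g * scale for g in grads]
    return grads


@dataclass
class Adam:
    """Adam optimizer over a flat parameter vector."""

    lr: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    m: Optional[np.ndarray] = field(default=None, repr=False)
    v: Optional[np.ndarray] = field(default=None, repr=False)
    t: int = 0

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(params)
            self.v = np.zeros_like(params)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return params - self.lr * mhat / (np.sqrt(vhat) + self.eps)
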