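# primer-mr

Learning **nonlinear, multi-risk-factor disease risk predictors** from a
healthy genetic cohort and external disease GWAS summary statistics — no
individual-level disease labels required.

## The idea

Two-sample Mendelian randomization (MR) estimates the causal effect of an
exposure on a disease by regressing variant effects on the outcome
(β<sub>o</sub>, with standard errors s<sub>o</sub>) on variant effects on
the exposure (β<sub>e</sub>), using inverse-variance weighting (IVW):

```
β_o ~ N(β_e α, σ² diag(s_o²)),     α̂ = Σ w_i β_e,i β_o,i / Σ w_i β_e,i²,   w_i = 1/s_o,i²
```

This package turns that estimator into a *training signal*. Given
individual-level data on N healthy individuals — K risk factors
X ∈ R<sup>N×K</sup>, covariates F, and S approximately independent genotype
dosages G — it defines a parametric aggregate risk function

```
f_φ(X) = Σ_k a_k · ELU(b_k x_k + c_k),     φ = {a_k, b_k, c_k}
```

computes the marginal, covariate-adjusted genetic effects β<sub>e</sub>(φ)
of each variant on e = f<sub>φ</sub>(X), and minimizes the IVW regression
negative log-likelihood

```
L_IVW(φ, α, σ²) = −log N(β_o | β_e(φ) α, σ² diag(s_o²))
```

with respect to φ, α, σ². Every step — the ELU warping, the marginal
regression (a fixed linear map of e), the Gaussian likelihood — is
differentiable, so the risk function that best *aligns* the predictor's
genetics with the disease GWAS is found by gradient descent. Inference is
Bayesian: Gaussian priors on φ, a mean-field Gaussian variational posterior
optimized by Adam on the ELBO (reparametrization trick, gradient clipping),
and posterior-mean risk scores for new individuals. With an identity warp
the method reduces exactly to multivariable MR (MVMR).

Because no disease labels from the training cohort enter the loss — only
external summary statistics — the approach respects the strict two-sample
discipline of MR.

## What is in the package

| module | contents |
| --- | --- |
| `primer_mr.model` | `PrimerModel` / `PrimerResults` — the differentiable IVW-aligned predictor (nonlinear and linear variants), variational training, scoring, JSON serialization |
| `primer_mr.core` | ELU risk function, marginal-genetic-effects operator, IVW loss and closed form, hand-derived gradients, Adam |
| `primer_mr.baselines` | UVMR-based and MVMR-based linear predictors, supervised reference model (LRM) with inner 5-fold CV |
| `primer_mr.gwas` | rank-inverse-normal transform, covariate-adjusted marginal scans, min-P multivariate clumping, allele harmonization |
| `primer_mr.simulate` | synthetic cohorts: HWE genotypes (optional LD blocks), heritable factors, warped-threshold causal contributions, horizontal pleiotropy, exact variance fractions |
| `primer_mr.evaluate` | Spearman/AUC metrics, repeated two-sample scenario harness, null calibration |
| `primer_mr.io`, `primer_mr.cli` | TSV formats and the `primer` command line (`simulate`, `gwas`, `clump`, `harmonize`, `fit`, `predict`, `baselines`, `evaluate`, `fixture`) |

## Worked example

```python
import numpy as np
import primer_mr as pm
from primer_mr.gwas import (batch_marginal_assoc, min_p_across_factors,
                            outcome_summary_from_cohort, rank_inverse_normal)

cfg = pm.SimulationConfig(n_individuals=4000, n_variants=80, n_factors=5,
                          n_causal_factors=3, variants_per_factor=16,
                          factor_heritability=0.35, var_explained_risk=0.35, seed=11)
cohort, outcome, truth = pm.simulate_cohort(cfg)
exposure, (outcome_cohort, y_out), (rows_exp, _) = pm.split_two_sample(
    cohort, outcome, seed=11, truth=truth)

K = len(exposure.factor_names)
Xr = np.column_stack([rank_inverse_normal(exposure.risk_factors[:, j]) for j in range(K)])
scans = batch_marginal_assoc(Xr, exposure.genotypes, exposure.covariates)
instruments = pm.clump(min_p_across_factors(scans), exposure.genotypes)

stats = outcome_summary_from_cohort(y_out, outcome_cohort.genotypes,
                                    outcome_cohort.covariates)
model = pm.PrimerModel.from_cohort(exposure, stats, instruments=instruments)
result = model.fit(epochs=500, seed=0)
print(result.summary())

scores = result.predict(exposure.risk_factors)
print(f"Spearman(prediction, simulated risk) = "
      f"{pm.spearman_corr(scores, truth.aggregate_risk[rows_exp]):.3f}")
```

Output:

```
IVW-aligned risk predictor (ELU-warped)
  factors: 5   instruments: 36
  alpha = 13.3893   sigma2 = 1.6392
  final negative ELBO = -28.7275 (500 epochs, lr 0.01)

  factor              a (mean+/-sd)         b                     c
  factor_1              0.0060 +/- 0.0728    0.0137 +/- 0.0701   -0.3727 +/- 1.0055
  factor_2              0.2068 +/- 0.0408    0.2065 +/- 0.0387   -0.8509 +/- 0.1935
  factor_3              0.2329 +/- 0.0366    0.2422 +/- 0.0390   -0.8704 +/- 0.1645
  factor_4             -0.1489 +/- 0.0413   -0.1504 +/- 0.0417   -0.6340 +/- 0.2908
  factor_5              0.0043 +/- 0.0745    0.0254 +/- 0.0775   -0.4164 +/- 1.0062

Spearman(prediction, simulated risk) = 0.885
```

Reading the table: the three causal factors (2, 3, 4 in this simulation)
receive outer weights `a` clearly separated from zero while the two
non-causal factors shrink toward the prior; for each causal factor the
product `a·b` is positive, i.e. the learned contribution is increasing in
the factor. The overall scale of (a, α) is not identified — only the
*ranking* of risk scores matters, and it recovers the simulated risk at
Spearman 0.885. The same pipeline is available from the shell via
`primer simulate | gwas | clump | harmonize | fit | predict`.

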