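# Methods

## Model

The predictor is an additive warped risk function over K risk factors,

e_i = f_φ(x_i) = Σ_k a_k · ELU(b_k x_ik + c_k),  ELU(z) = z (z ≥ 0), e^z − 1 (z < 0),

with parameters φ = (a, b, c) ∈ R^{3K}. Each factor contributes a smooth
monotone-warped term: the inner affine map b_k x + c_k places a soft
threshold, the ELU suppresses contributions below it, and a_k sets the
direction and magnitude. Factors are rank-inverse-normalized (Blom offsets,
(r − 3/8)/(N + 1/4)) before entering the model, so x is on a standard-normal
scale and the b, c parameters are comparable across factors; the fitted
transform is stored as training quantiles and applied to new individuals by
monotone interpolation.

The training signal is two-sample MR. For S approximately independent
instrument variants, the marginal covariate-adjusted genetic effects of the
predictor, β_e(φ)_s = (g̃_s · ẽ)/(g̃_s · g̃_s) with g̃, ẽ residualized on the
covariates F, are matched to external outcome GWAS effects β_o through the
IVW likelihood

L_IVW(φ, α, σ²) = −log N(β_o | β_e(φ) α, σ² diag(s_o²)).

Two facts make this trainable end to end without an autodiff framework:

1. Residualization is a symmetric idempotent projection, so
   β_e = A e for the fixed matrix A = D⁻¹ (M G)ᵀ (D the residual dosage
   norms, M the projector). A is precomputed once per cohort; the adjoint
   Aᵀ carries loss gradients back to e.
2. The remaining chain (ELU forward, Gaussian likelihood) has short
   closed-form derivatives. All gradients are written out analytically in
   `primer_mr.core` and validated against central finite differences to
   1e−4 relative in the test suite.

## Inference

Parameters φ carry independent Gaussian priors N(0, τ²) (default τ = 1) and
a diagonal-Gaussian variational posterior q(φ) = N(μ, diag(s²)), trained by
maximizing the ELBO

E_q[−L_IVW(φ, α, σ²)] − KL(q ‖ p)

with the reparametrization trick (default 8 Monte Carlo draws per step,
full-batch over all instruments), Adam at learning rate 0.01, global
gradient-norm clipping at 1, and 1000 epochs by default. The nuisance
parameters are point-optimized alongside the posterior: α directly, σ² on
the log scale (an alternative would marginalize them under conjugate
priors; the point treatment keeps the objective simple and leaves rank
predictions unchanged up to scale). Initialization: posterior means for a,
b from N(0, 0.1²), c = 0, posterior log-SD = log 0.1, α at the magnitude of
the closed-form IVW slope evaluated at the initial parameters, σ² = 1.
Predictions for new individuals are posterior means, estimated from 256
posterior draws with a fixed internal seed so scoring is deterministic.

The (a, α) scale ambiguity is left unconstrained: multiplying a by any
positive constant and dividing α by the same constant leaves the likelihood
(and all rank metrics) unchanged. Tests check this invariance explicitly.

`linear=True` removes the warping (f(X) = Xa); the machinery then reduces
to multivariable MR, and the package verifies the fitted weights agree with
the closed-form inverse-variance-weighted least squares solution.

## Instrument selection and harmonization

Instruments are chosen on the exposure cohort only: per-factor marginal
scans (joint OLS coefficient of dosage adjusting for covariates, computed
by Frisch–Waugh residualization; p-values from the two-sided normal
approximation, adequate at the sample sizes used here), followed by greedy
clumping on the per-variant minimum p-value across factors with defaults
P < 5×10⁻⁸, r² < 0.05 within a ±5000 kb window. r² is the squared Pearson
correlation of dosages in the exposure cohort; min-P ties break by
(chromosome, position) for determinism. Outcome summary statistics are
harmonized by variant id: palindromic (A/T, C/G) variants are always
dropped, swapped alleles flip the outcome effect sign, other allele
combinations are dropped as mismatches.

## Baselines

* **UVMR-based**: a_k is the univariate IVW slope on factor k's own
  clumped genome-wide-significant instruments, zeroed unless the factor has
  ≥ 5 instruments and its slope passes Bonferroni-corrected significance
  (α = 0.05 over all K factors — the conservative denominator).
* **MVMR-based**: weighted least squares of β_o on the S×K matrix of factor
  effects with weights 1/s_o², no intercept; rank-deficient designs are
  rejected with a condition-number diagnostic.
* **LRM**: the same ELU risk function trained directly on individual-level
  labels (MSE, or cross-entropy through a logistic link for binary onset),
  with learning rate ∈ {0.01, 0.001} and weight decay ∈ {0, 10⁻⁴, 10⁻²}
  chosen by inner 5-fold cross-validation. It upper-bounds what the
  label-free MR-based predictors can achieve.

## Synthetic cohorts

The generator emulates the statistical structure of a biobank-style study:

* Genotypes: additive dosages as two Bernoulli(maf) haplotypes per variant
  (Hardy–Weinberg equilibrium), maf ~ U(0.1, 0.5), variants spaced ~11 Mb
  apart over 22 chromosomes so independent variants never share a clumping
  window. Optional equicorrelated Gaussian-copula LD blocks exist for the
  clumping test surface.
* Risk factors: each factor is a genetic score over its assigned variants
  (default 20 per factor, effects N(0,1)) plus Gaussian noise, empirically
  rescaled so the score explains the requested heritability (default 0.3),
  plus a small contribution (coefficient 0.1) from two standard-normal
  nuisance covariates so covariate adjustment is exercised.
* Outcome: sum of (i) a linear combination of warped causal-factor
  contributions, (ii) a horizontal-pleiotropy term — a direct genetic score
  over a random variant subset — and (iii) Gaussian noise. Components are
  sequentially orthogonalized, standardized and scaled to the square roots
  of the requested variance fractions, so realized fractions are exact
  in-sample regardless of the warping nonlinearity.
* Warping: a smooth thresholded ramp softplus(sharpness·(x − threshold)) —
  negligible below the threshold, slope → sharpness above it — optionally
  composed with s·tanh(u/s) for a finite saturation asymptote s. Defaults:
  threshold 0.5, sharpness 2, no saturation; on rank-normalized factors the
  threshold at 0.5 puts roughly a third of individuals in the active regime.
* Two-sample split: even disjoint split (odd N: extra individual to the
  exposure side, which carries the heavier estimation).

What the generator does **not** emulate: population structure and
relatedness, LD beyond the explicit block fixtures, imputation uncertainty,
binary/ascertained outcomes, correlated real-trait panels. Passing tests
therefore demonstrate correctness of the machinery and recoverability under
the stated generative assumptions, not real-data performance.

## Evaluation harness

Per scenario repeat: simulate, split two-sample, select instruments on the
full exposure cohort, estimate outcome summary statistics on the outcome
cohort, train every method on 80% of the exposure cohort, and score the
held-out 20% against the *noiseless* simulated aggregate risk with Spearman
correlation (the supervised LRM receives the exposure-cohort outcome values
as labels, mirroring its access to follow-up data). Means ± standard errors
(SD/√R) are aggregated over 10 repeats by default; all per-repeat seeds
derive from one base seed via named streams, so scenarios are deterministic
and order-independent.

Null calibration uses a configuration with zero causal factors (risk
variance 0). The simulated risk is then constant, so held-out predictions
are correlated against an independently redrawn random ranking; each
MR-based method passes iff |mean| ≤ 2·SE. Feeding a non-null configuration
instead scores against the true risk, making an effective predictor fail
the check — a positive control.

Binary-outcome evaluation (AUC via the Mann–Whitney formulation) is
exercised on synthetic liability-threshold labels (top 10% of the noisy
outcome as cases), clearly labelled as synthetic.

## Standard study conditions and problem sizes

The standard nonlinear scenario used throughout: 8000 individuals (4000
per cohort after the even split), 200 variants, 10 factors of which 5
causal, factor heritability 0.3, risk variance fraction 0.3, no pleiotropy;
the pleiotropy variant adds a 0.1 pleiotropy variance fraction over 10% of
variants. Scenario training in the harness and acceptance script uses 300
epochs (recorded in run manifests); the library default remains 1000. The
reduced epoch count converges to indistinguishable held-out rankings on
these problem sizes while keeping a 10-repeat, 5-method scenario to about
a minute of CPU.

## Numerical choices and edge cases

* Constant phenotypes: association scans return β = 0, p = 1.
* Residualized dosage columns with (near-)zero norm are excluded with a
  warning everywhere they would make a marginal effect undefined.
* σ² > 0 enforced by log-scale parameterization; s_o ≤ 0 rows are rejected
  (loss) or dropped with a logged count (readers).
* Ties: average ranks in both the rank-inverse-normal transform and the
  Spearman/AUC metrics; clumping ties broken lexicographically.
* Non-finite training objectives abort with the epoch index and last
  nuisance values rather than continuing silently.

## Known limitations

* The IVW loss ignores uncertainty in β_e (only s_o enters), as in the
  underlying regression model; weak-instrument bias is therefore inherited.
* No pleiotropy-robust estimators (median, MR-Egger) — the nonlinear model
  is still an IVW-type estimator and degrades gracefully, not immunely,
  under directional pleiotropy.
* Mean-field VI understates posterior correlations between a_k, b_k, c_k of
  the same factor; reported per-parameter SDs are best read qualitatively.
* The CLI covers the synthetic TSV dialect only; no VCF/PLINK binary
  readers.
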