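# Methods

## Model

Disease counts are observed at the individual level inside `M` contiguous
regions. For subject `i` of region `j`, conditional on a region effect
`b_j`,

    y_ij | b ~ Poisson(mu_ij),     log mu = X beta + Z U gamma + Z b,

where `X` (`n x p`, with intercept) holds individual covariates, `U`
(`M x q`, no intercept) holds group covariates, and `Z` is the `n x M`
membership ("replication") matrix. The spatial effect follows the Leroux
conditional-autoregressive family: `b ~ N(0, D)` with precision

    D^-1 = sigma^-2 { (1 - lambda) I + lambda R },

`R` being the intrinsic autoregression matrix of the adjacency graph
(`R_jj = m_j`, `R_jj' = -1` for neighbours). `lambda = 0` gives exchangeable
effects, `lambda -> 1` the intrinsic autoregression; because `R` is singular,
estimation restricts `lambda <= 1 - 1e-6` so that `D` exists.

## Estimation

Maximization of the penalized quasi-likelihood (Laplace/PQL approximation of
the integrated likelihood) is organized as a two-level backfit so that no
factorization ever exceeds `p x p` or `M x M`:

* **Step 0.** Poisson GLM of `y` on `X` alone (IRLS with step-halving):
  initial `beta`.
* **Step 1.** Aggregate: counts `Y_c = Z'Y`, offset
  `O1 = log(Z' exp(X beta))`. Fit the group-level Poisson mixed model for
  `(gamma, b)` by penalized IRLS at fixed `theta = (sigma^2, lambda)`, and
  update `theta` by maximizing the restricted likelihood (REML) of the
  working response `z = U gamma + b + W_c^{-1}(Y_c - mu_c)` under
  `z ~ N(U gamma, D + W_c^{-1})`, profiled over `gamma`. `sigma^2` is
  optimized on the log scale and `lambda` on a bounded logit scale
  (L-BFGS-B on the 2-vector); the REML criterion is evaluated through the
  identity `V^{-1} = W - W(D^{-1} + W)^{-1} W` and the precomputed
  eigenvalues of `R`, so each evaluation costs one `M x M` Cholesky.
* **Step 2.** Poisson GLM of `y` on `X` with offset
  `O2 = Z(U gamma + b)`: updated `beta`.

Steps 1–2 repeat until the largest relative change across
`(beta, gamma, b, theta)` falls below `1e-6` (cap 500). The fixed point
solves the joint penalized score equations, so the backfit agrees with a
single stacked IRLS over `[X | ZU | Z]` apart from rounding — the test
suite checks this to `1e-4` against a dense joint solver on instances small
enough to stack.

### Convergence acceleration

The plain Gauss–Seidel cycle converges geometrically with a ratio that
approaches 1 when the intercept and the spatial effect are strongly coupled
(often 70–300 iterations at `M = 400`). Two purely-numerical devices keep
the fixed point unchanged while shrinking the iteration count to ~5–15:

1. one PQL/REML alternation per outer cycle (inexact Gauss–Seidel), and
2. every third cycle, one joint Fisher-scoring step: the working linear
   mixed model is solved for `(beta, gamma, b)` in a single shot through
   the same Woodbury algebra used for the standard errors (cost: one
   `M x M` factorization plus `p + q` weighted aggregations), which
   eliminates the slowly-decaying error mode that the alternating cycle
   cannot damp.

A non-finite or wild joint solution (any coefficient beyond 50 in absolute
value) is discarded for that cycle. If the iteration stops improving for 12
cycles the best iterate is restored and the joint steps spaced out
threefold; after three stalls the fit restarts with the conservative scheme
(fully converged Step 1 per cycle, no joint steps). All replicate studies
reported here ran with these defaults.

## Standard errors

Naive step-wise covariances ignore that the other level's coefficients are
estimated. At convergence the corrected joint covariance of
`(beta, gamma)` is `Q = (C' V^{-1} C)^{-1}` with `C = [X | ZU]`,
`V = Z D Z' + W^{-1}`, `W = diag(mu)`. `V` (`n x n`) is never formed: by the
Woodbury identity all blocks reduce to `X'WX`, `X'WZ` and `M x M` algebra
(`K = I + Z'WZ D`), which is also what makes the computation distributable.
The BLUP covariance of `b` is the inverse of the group-level penalized
information `(W_c + D^{-1})^{-1}`, treating the fixed effects as known; the
extra variability from estimating `theta` is ignored throughout.

An approximate conditional AIC is reported as `-2 l_c + 2 rho` where `l_c`
is the conditional Poisson log-likelihood at the fitted means (dropping the
`log y!` constant) and `rho = p + q + tr[(W_c + D^{-1})^{-1} W_c]` counts
fixed plus effective random-effect degrees of freedom. The reference the
definition paraphrases gives no closed formula, so this choice is a
documented convention of this package, not a reproduced number.

## Synthetic-data generator

`simulate_dataset` emulates an areal disease-mapping study on a rook-adjacent
`20 x 20` lattice (400 regions) with, per region, a subject count uniform on
a configurable range (defaults cover two scenarios: 10–1000 and 10–50), a
binary covariate ("sex") with per-region prevalence uniform on (0.45, 0.55),
a 6-level category ("age band") with fixed probabilities
(0.02, 0.04, 0.10, 0.19, 0.26, 0.39) reference-coded to 5 contrasts, a
continuous covariate uniform on (0.2, 1), one standard-normal group
covariate, and `b` drawn exactly from the Leroux covariance (through the
precision Cholesky; `lambda = 0.99` uses the exact near-intrinsic
covariance, never the singular limit). Default coefficients:

    beta = (-0.2, -2.5, 0.7, -2.0, -1.5, 0.2, 0.5, 0.8),  gamma = 0.2,
    sigma = 0.4,   lambda in {0, 0.25, 0.50, 0.75, 0.99}.

The age-band probabilities approximate the age mix of an adult cancer
cohort; mean-estimate recovery is insensitive to this choice. Replicate `r`
uses seed `base_seed + r`, so studies are bit-reproducible.

What the generator does **not** emulate: overdispersion beyond the Poisson
level, within-subject repeated admissions, informative region sizes,
covariate measurement error, or irregular adjacency graphs (real postal-area
graphs have highly variable neighbour counts). Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
stated design, not robustness to those real-data features.

## Comparison ("standardization-only") method

The traditional areal analysis enters individual covariates only through
indirect standardization: pooled stratum rates `r_s` over sex x age band
give expected counts `E_j = sum_s n_js r_s` (totals conserved by
construction), and a group-level Leroux CAR model is fitted to `Y_c` with
offset `log E_j`, an intercept and the group covariate. A stratum with no
events falls back to the pooled rate with a warning. Standardized incidence
ratios are `SIR_j = O_j / E_j`; the CLI flags regions with `SIR > 3`.

## Study sizes used by the tests and the acceptance script

Replicate studies in `tests/test_acceptance.py` run the full benchmark
design at 40 replicates per `lambda` (small-sample scenario, all five
`lambda` values, both methods) and 20 replicates (large-sample scenario,
`lambda in {0, 0.50}`); `scripts/acceptance.py` uses 20 and 12. Every
mean-estimate comparison uses a 3 Monte-Carlo-SE band computed from the
replicates actually run, so reduced sizes widen the band in a statistically
calibrated way. The backfit/joint-IRLS and Woodbury checks use `M = 25`
lattices with `n` up to ~520, the largest sizes at which the dense oracles
are comfortably formed.

## Numerical choices and degenerate inputs

* GLM IRLS: intercept initialized at `log(mean(y) + 0.5) - mean(offset)`;
  relative deviance tolerance `1e-10` (backfit uses `1e-11`), cap 50,
  step-halving on deviance increase; linear predictors above 500 rejected
  during halving to avoid overflow.
* Penalized inner solve: objective (Poisson kernel minus quadratic penalty)
  is non-decreasing by step-halving; solved via Cholesky of `D^{-1} + W_c`.
* `theta` REML: L-BFGS-B, `gtol 1e-6`, start `(sigma^2, lambda) =
  (0.1, 0.5)` unless warm-started; `lambda` capped at `1 - 1e-6`; the
  boundary `lambda = 0` is admissible.
* Regions with zero subjects are rejected (the aggregation offset would be
  `log 0`); isolated regions (no neighbours) are allowed and flagged with a
  warning.
* Covariances are symmetrized and checked by Cholesky; `lambda = 1` in
  `leroux_covariance` raises a singularity error instructing the caller to
  use `1 - 1e-6`.

## Known limitations

* The intercept `beta_0` is poorly identified under strong spatial
  correlation (it trades off against the level of `b` as `lambda -> 1`);
  its estimate attenuates and it is excluded from recovery checks.
* PQL is a Laplace-type approximation: with very sparse counts its variance
  components can be biased; the REML working-model update used here is
  close to unbiased in the benchmark design but need not reproduce the
  bias pattern of other PQL variants.
* Variance of `theta`-hat is not propagated into any reported standard
  error.
* The backfit requires every region to have at least one subject and a
  full-rank individual design; small samples with empty covariate levels
  (quasi-complete separation) have no finite MLE and are rejected upstream.
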