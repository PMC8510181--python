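# Methods

## Structural and statistical model

Vancomycin disposition is modeled as a one-compartment system with zero-order
intravenous infusion input and first-order elimination. For an infusion of rate
R starting at t₀ with duration T, the concentration contribution is
(R/CL)(1 − e^(−kₑ(t−t₀))) during the infusion and exponential decay afterwards;
multiple doses superpose (linear kinetics). All closed forms are checked in the
test suite against an independent adaptive ODE integration.

Typical values carry fixed allometry — clearance scales with wt^0.75, volume
with wt^1.0 — before any estimated covariate effect. Covariates enter clearance
or volume as median-normalized power terms (continuous) or multiplicative
factors (categorical; male = 1, biliary atresia = 1). The final model has
serum creatinine and days-from-liver-transplantation (DFLT) power terms on
clearance, with fixed reference values 0.16 mg/dL and 17 days (the study
medians) so the coefficients stay interpretable across datasets. DFLT is
floored at 1 day: (0/17)^θ is undefined, and one day is the smallest
physiologic resolution of the covariate; the floor is configurable.

Between-subject variability is diagonal and exponential on CL and V. Residual
error supports additive, proportional, combined (default for model building)
and exponential (log-scale additive, including the Jacobian term in the OFV so
model comparisons remain valid) forms. Percent reporting of ω and σ uses
100·SD, not CV%; at the magnitudes involved the two differ by a few points and
the convention is stated here once.

Units: h, mg, L, µg/mL (≡ mg/L) throughout; doses are prescribed per kg and
converted at administration time.

## Estimation

The per-subject marginal likelihood integrates the conditional density over
(η_CL, η_V). The package uses a Laplace approximation:

1. **Inner problem.** The conditional mode is found by a batched, damped
   Newton search over all subjects simultaneously. Gradients of the model
   predictions with respect to η are analytic. The first iterations use a
   Fisher-scoring Hessian (Gauss–Newton plus the ½·dv·dv′/v² variance-
   information term — without the variance term the search zigzags under a
   dominant proportional error); later iterations switch to the exact Hessian
   obtained by central differences of the analytic gradient where it is
   positive definite. Steps are trust-region capped at 2 (log-scale), a
   monotone backtracking line search guarantees descent, and the search always
   starts at η = 0 so the objective is an exactly deterministic function of
   the population parameters.
2. **Curvature.** The Laplace log-determinant uses the exact conditional
   Hessian at the mode, falling back to the Fisher matrix for the rare
   subject where the exact matrix is not positive definite.
3. **Outer problem.** −2·log marginal likelihood (OFV; per-subject
   contributions combined with exact summation, so the total is independent
   of subject order) is minimized over (θ, ω, σ) with variance parameters on
   the log scale. Because a sparse subject's conditional posterior can be
   multimodal, the OFV is only piecewise smooth in the population parameters;
   a finite-difference L-BFGS-B stage therefore provides cheap initial
   descent and a derivative-free Powell stage (repeated until improvement
   falls below 0.1 OFV units) does the final convergence. A fit that stops
   making progress is reported as converged; a fit that is still improving
   when iteration limits bind is reported `converged=False` with best-found
   values, which the bootstrap counts as a failure.

Standard errors come from a central-difference Hessian of the OFV with a wide
step (0.08 on the log scale): the surface's small mode-switching kinks make
machine-resolution curvature meaningless, so precision is measured on the
likelihood-ratio scale. Empirical Bayes estimates (EBEs) are the inner modes at
the final parameters; η-shrinkage is 1 − SD(EBE)/ω and ε-shrinkage is
1 − SD(IWRES).

The default initial values are deliberately neutral (θ_CL 0.5, θ_V 0.7, ω 0.3,
σ_prop 0.3) rather than any published estimate.

**Accuracy contract.** On small instances (≤3 subjects, ≤3 observations) the
Laplace OFV agrees with a 64-node adaptive Gauss–Hermite quadrature oracle to
better than 0.5 units (observed worst case ≈ 0.3); the oracle lives in the
test suite and shares no code with the engine. Exact bit-compatibility with
any commercial FOCE implementation is explicitly not a goal.

## Covariate selection

Univariate screening records the ΔOFV of each single-covariate extension of
the allometric base model. Forward inclusion repeatedly adds the candidate
with the largest OFV drop while the drop exceeds 3.84 (χ²₁, p < 0.05);
backward elimination removes any retained effect whose deletion raises the
OFV by less than 7.88 (p < 0.005). Candidate fits that fail to converge are
logged and skipped. Under a null covariate the forward step fires at its
nominal ~5% rate (checked over 200 simulated replicates).

## Synthetic populations

No patient-level data ship with the package; the generator emulates the study
population's *marginal* structure:

- Weight, sCr, DFLT (rounded to whole days), albumin and ALT are truncated
  log-normals matched to the published medians and IQRs
  (log-SD = (ln Q3 − ln Q1)/1.349) and truncated at the published ranges.
- Height (26.7·wt^0.435) and age (0.62·wt^1.39 months) are smooth growth-curve
  approximations of weight with log-normal noise (SD 0.05 and 0.25), clipped
  to the published ranges — an emulation of the weight–height–age dependence,
  not a reconstruction of the joint distribution. Other covariates are drawn
  independently, so covariate correlations present in the real cohort (e.g.
  DFLT with renal function) are absent; stratified dosing-simulation
  *percentages* are therefore approximations and only their orderings are
  asserted anywhere.
- Sex (44.7% male) and biliary atresia (52.2%) are Bernoulli draws.
- Each of n patients contributes 1 + Poisson(0.677) treatment episodes
  (matching 270 episodes among 161 patients); episodes are simulated
  independently, including fresh random effects — a simplification the real
  repeated-measures structure does not share.
- Dosing follows institutional practice: 15 mg/kg q6h (q8h from age 13 y),
  1-h infusions (infusion length is not reported; 1 h is standard practice
  and configurable per dose). Five doses are given so the TDM trough —
  drawn 5 min before the fourth or fifth dose — always exists; additional
  sampling times (Poisson mean 3.3 per episode) are uniform over the episode,
  giving ≈4.3 observations per episode (≈1,150 total at study size).
- Observations are y = f·(1+ε_prop) + ε_add. With σ_prop = 56.5%, about 4% of
  draws fall below 0.1 µg/mL; they are floored there and flagged as
  below-quantification (the flooring is a generator policy, the likelihood
  treats them as ordinary values).

What passing tests show, and don't: parameter recovery on these populations
demonstrates the estimator is consistent under the stated model at the study's
size and design; it cannot certify behaviour under model misspecification,
informative sampling, or the covariate correlations of the real cohort.

## Validation tools

- **Bootstrap**: subjects (treatment episodes) resampled with replacement,
  refit warm-started at the original estimates (fast; can in principle mask
  multimodality, which is why the acceptance check also verifies medians
  against point estimates), percentile 2.5/50/97.5 summaries over converged
  replicates, convergence rate reported, warning below 50%.
- **VPC**: replicate datasets simulated at the original design; observed
  5th/50th/95th percentiles compared with their simulation bands in 8
  quantile-spaced bins of time-after-most-recent-dose (binning is a package
  choice; stratification by regimen is not applied). The headline number is
  the fraction of observations inside the pointwise simulated 90% interval.
- **GOF**: PRED (η = 0), IPRED (at EBEs), IWRES, and CWRES from the standard
  first-order expansion about the EBEs, whitened per subject by the full
  G·Ω·Gᵀ + diag(v) covariance.

## Dosing simulations

Virtual subjects get covariates from the generator (or any user cohort) and
random effects from ω. Steady-state trough uses the closed form; AUC₂₄ uses
the steady-state identity daily dose/CL (an optional first-24-h trapezoidal
window exists because the original analysis does not state which window was
used; steady state is the default and the convention in this literature).
Targets default to trough ≥ 10 µg/mL and AUC₂₄/MIC ≥ 400 at MIC 0.5/1/2 µg/mL
(≥ rather than > — a measure-zero choice in a continuous simulation,
configurable). Strata: DFLT < 14 vs ≥ 14 days, and Schwartz creatinine
clearance k·height/sCr with k = 0.45 (< 1 y), 0.55 (children and adolescent
females), 0.70 (adolescent males), binned at 20/40/60/90 mL/min/1.73 m².
CLCr is stratification-only; the PK model uses sCr and DFLT directly.
Empty strata report NA, never zero.

## Problem sizes and numerical defaults

Chosen sizes, stated once as package policy: the parameter-recovery experiment
runs at the full study size (161 patients, one fit); the quadrature-agreement
check uses 10 instances of ≤3 subjects × ≤3 observations; null-covariate
selection calibration uses 200 replicates of 30 single-episode subjects;
bootstrap self-consistency uses a 40-episode cohort with 200 resamples
(scaled from the original 1,000); VPC uses 400 simulation replicates; dosing
orderings use 4,000 profiles. Inner Newton tolerance 1e-7 on the gradient
sup-norm; outer L-BFGS-B finite-difference step 1e-4 (log scale); Powell
termination at 0.1 OFV units; ω active threshold 1e-6; residual variance
floored at 1e-14.

## Known limitations

- Laplace (like FOCE) is biased for variance components under sparse, very
  noisy designs; with ~4 observations per episode and a 56% proportional
  error, single-replicate ω estimates can deviate 20–30% from truth even
  though fixed effects recover well.
- Mode-based empirical Bayes estimates are skewed upward in clearance when a
  proportional error term dominates: the conditional objective's ln v(η)
  term rewards lower predictions, i.e. higher clearance, so the population
  mean of exp(η̂_CL) exceeds the symmetric-shrinkage value e^(SD²/2) and
  EBE-averaged CL/kg summaries run ~15% above the typical-value average at
  this study's noise level (the effect disappears at moderate residual
  error). This is a property of posterior modes themselves — the inner
  objective matches the quadrature-verified posterior — not an implementation
  artifact; mean-based summaries of posthoc clearance should be read with
  that skew in mind.
- No inter-occasion variability, no correlated ω blocks, no time-varying
  covariates within an episode, no two-compartment option, no BQL likelihood
  (M3-style) handling.
- Bootstrap warm starts and the piecewise-smooth OFV mean reported optima are
  stationary within ~0.1 OFV units, not certified global minima.
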