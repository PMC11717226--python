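# Methods

This note records the model conventions, the numerical choices, the
design of the synthetic studies, and what the passing tests do and do
not establish.

## Model conventions

The equation-error VARX model is

    y(t) = Σ_{l=1..n_a} A(l) y(t−l) + Σ_{l=0..n_b−1} B(l) x(t−l) + e(t)

* `A` is stored as a tensor `[lag, target, source]` with lags 1..n_a;
  `B` as `[lag, target, input]` with lags 0..n_b−1 (the input acts
  instantaneously at lag 0). "Row = target" throughout.
* Either order may be zero: `n_a = 0` is a pure moving-average
  (temporal-response-function) model, `n_b = 0` a pure VAR.
* Simulations treat all pre-history samples (t ≤ 0) as zero. The
  estimator independently discards every sample without a complete
  history, so this warm-up convention never leaks into fits.
* The innovation `e(t)` is white Gaussian, i.i.d. across time and
  channels; it may be supplied explicitly (reproducibility) or drawn
  from a seeded generator.
* Instability is detected, never repaired: the simulator raises with
  the first non-finite time index, `impulse_response` warns when the
  companion-matrix spectral radius reaches 1, and nothing in the
  estimator enforces a stable `Â`.

The output-error generator runs the same recursion noise-free on a
hidden state `z(t)` driven only by the input, and observes
`y(t) = z(t) + e(t)`; the noise never enters the recursion. Only
simulation is provided for this model — its estimation is a
non-convex problem outside this package's scope.

## Estimation

A sample contributes to the normal equations iff its target `y(t)`,
the AR window `y(t−1)..y(t−n_a)`, and the MA window
`x(t)..x(t−n_b+1)` are all finite and lie within a single recording
segment. Missing values (NaN, or NA/empty fields in input files)
therefore knock out exactly the samples whose predictor window
touches them. Cross-products are accumulated over all valid samples;
reduced models reuse these cached matrices, so the data are scanned
once per fit.

The ridge penalty is `γ · diag(R_xx)`, which regularizes every
predictor equally regardless of scale. `γ` is dimensionless with
default 0 and is never selected automatically; a cross-validation
helper (`cv_gamma`) exists but is opt-in, because any automatic
γ-versus-T schedule would be an invention. The penalized system is
solved by Cholesky factorization with a least-squares fallback (and a
warning) when it is singular — at γ = 0 that warning is the signal of
rank deficiency.

Gaussian lag bases for `B`: `n_basis` bumps with centers equally
spaced over lags 0..n_b−1 (endpoints included) and standard deviation
equal to the center spacing, floored at 0.5 lag so no column
degenerates; columns are normalized to unit maximum so that
`diag(R_xx)` scaling stays meaningful. The compression is applied
directly to the normal equations (`R → Wᵀ R W` on exogenous blocks);
reduced models under compression drop the `n_basis` compressed
predictors of a channel and the chi-square test uses `n_basis`
degrees of freedom, keeping the reduced model nested in the fitted
one.

## Inference

* At γ = 0 the plain deviance `D = T_used · log(σ̂²_r/σ̂²_f)` is used.
* At γ > 0 the de-biased deviance
  `D = T′ log(σ̂²_r/σ̂²_f) − b_r + b_f` with `T′ = T_used − N` (the
  full model's N for both terms) and
  `b = diag(R_xeᵀ R_xx⁻¹ R_xe)/σ̂²`, where `R_xe = R_xy − R_xx Ĥ` is
  the predictor–residual cross-product (identically zero at γ = 0).
  The quadratic form is the excess residual sum of squares the shrunk
  estimate carries over the least-squares optimum; dividing by σ̂²
  puts it on the deviance scale. This is the second-order expansion
  of the profiled Gaussian log-likelihood around the optimum, and it
  is the scaling that empirically restores the null rejection rate to
  α for γ up to ≈ 0.3 (beyond that the expansion degrades and the
  corrected test drifts anticonservative; the simulation study in
  `debias_calibration_study` measures this directly).
* `R_xx⁻¹` in `b` is the raw inverse; the regularized
  `(R_xx + γΓ)⁻¹` variant is available behind
  `use_regularized_inverse` for sensitivity checks (in our
  simulations the two are indistinguishable).
* A slightly negative de-biased statistic is clamped to 0 (p = 1)
  before the chi-square lookup — conservative and keeps p in range.
* No multiple-testing correction is applied by default; the full
  p-value matrices are emitted and `bh_fdr` is provided as an opt-in
  helper.
* A variable with zero variance after masking (as source) or zero
  residual variance (as target) is excluded from testing with a
  logged warning; its entries are NaN, never a crash.

## Synthetic studies: what they emulate and how

All studies draw per-replicate seeds from a spawned seed sequence and
are bit-reproducible given (seed, reps, config).

**Parameter recovery** (`recovery_study`): one realization of a
3-channel system with one standard-normal input, AR order 3,
instantaneous input effect, T = 1000, no regularization. True AR
entries are uniform on ±0.3 (redrawn until the spectral radius is
below 0.95), input coefficients standard normal. Reported: the
elementwise correlation and maximum absolute error between true and
estimated filters.

**False-discovery-rate study** (`fdr_study`): 1000 replicates of a
6-channel model (d_x = 1, n_a = n_b = 2, T = 1000), input
coefficients standard normal, AR entries ±0.05 with random sign, the
self-history of channel 2 and the input effect on channel 5 truly
zero. Unit-variance Gaussian innovations and input. The two null
channels estimate the false-positive rate of the deviance test; all
other channels estimate power. A known property of this
configuration: the power of the endogenous-channel tests is bounded —
the noncentrality of the test for a ±0.05 coupling is approximately
`T · n_a · 0.0025 ≈ 5` *independently of the innovation and input
scales* (the removed lags' unique information beyond the retained
predictors is essentially the source channel's own innovations,
weighted by the coupling), giving asymptotic power ≈ 0.5–0.8, while
the standard-normal exogenous couplings are detected in essentially
every replicate. The study reports both the pooled null rate and the
minimum/mean nonzero-channel rates so this asymmetry is visible
rather than hidden.

**De-bias calibration** (`debias_calibration_study`): 1000 ridge fits
(γ = 0.1) of a 4-channel model with N = 20 parameters against
T = 300 samples, one truly-zero channel. Reports the null rejection
rate of the corrected and the plain statistic and the fraction of
replicates on which the two decisions disagree.

**Causal-structure study** (`structure_study`): two endogenous
channels with a one-directional coupling y1 → y2 (0.3 at lag 1) and a
conditioning variable x that is a common cause (x → y1, x → y2 with
filter [1.0, 0.5, 0.25]), a collider (x(t) = 0.5·(y1(t) + y2(t)) +
noise), or independent; n_a = n_b = 3, T = 5000, 500 replicates,
unit noise everywhere. Each replicate is fitted with and without x
offered as exogenous input; reported are the detection rate of
y1 → y2 (power) and the rejection rate of the absent reverse path
(false positives). Two deliberate asymmetries in the true dynamics
are load-bearing:

* y2 carries a self-history filter ([0.3, 0.2, 0.1]) because the
  collider mismatch only produces spurious effects when the collided
  channel has predictable structure of its own — with a memoryless
  y2, the retained predictors already account for everything the
  collider mixes in, and the spurious effect vanishes. The collider
  is contemporaneous for the same reason: a lagged collider's
  ingredients are themselves retained predictors, so conditioning on
  it is harmless; only the instantaneous mix, entering through the
  model's lag-0 input term, conditions on information the model
  cannot otherwise reach.
* y1 carries no self-history, so under output-error generation its
  hidden state is fully determined by the n_b modeled input lags.
  With y1 self-recursion the hidden state depends on the infinite
  input past, the finite-lag fit truncates it, and the reverse-path
  test turns spurious at large T — a model-truncation artifact, not
  the property under study.

Under output-error generation the scenarios without input drive
(independent, collider) have a constant hidden state, so the observed
series is pure observation noise: the tests are then trivially null
(power ≈ α). This is the price of keeping the output-error generator
exactly the noise-free-recursion model; a hidden innovation drive was
deliberately not added, because measurement noise on an
innovation-driven recursion makes the reverse path genuinely spurious
and would change what the study measures.

Expected outcomes, reproduced by the acceptance suite: reverse-path
false positives ≈ 0.05 whenever x is included as input (common cause
or independent, either noise model) and when an independent x is
omitted; ≈ 1 when a common cause is omitted (the classic unobserved
confound) and when a collider is offered as input (the classic
conditioning artifact).

## What passing tests do and do not show

The generators produce stationary, linear, Gaussian data with white
innovations — exactly the assumptions of the chi-square calibration.
Real recordings violate them in known ways (1/f spectra,
non-stationary transients, shared measurement noise, unobserved
channels), and the deviance test inherits every such violation as a
potential spurious link. Calibration on these studies therefore
validates the implementation of the formalism, not its applicability
to any particular dataset. Time-reversal controls are deliberately
not implemented; frequency-domain variants, L1/state-space
regularization, automatic order selection, and estimation of the
output-error model are out of scope.

## Problem sizes

Default study sizes (1000 replicates at T = 1000 for calibration,
500 at T = 5000 per structure scenario) were chosen so a full
validation pass completes in about a minute on a single CPU while
keeping the binomial standard error of a 0.05 rate below 0.01; the
`reps` and `T` arguments scale all of them.
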