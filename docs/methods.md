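# Methods

## Model and data structure

Patients enter the trial at calendar times R_j (staggered accrual),
are randomized to a control arm (0) or one of K treatment arms with
probabilities p_0, …, p_K, and have a latent survival time T_j and
censoring time C_j measured from entry. At a calendar time t only
Y_j(t) = min(T_j, C_j, t − R_j) and the event indicator are observable;
`Snapshot` materializes exactly this view, and every analysis operates
on snapshots. Hazards are proportional: arm k multiplies the control
hazard by HR_k, i.e. a Cox model with K treatment indicators, which is
equivalent to K two-arm Cox models sharing the control baseline.

The partial likelihood (Breslow tie handling) with its score and
observed information is implemented directly rather than through a
fitting library because the estimators downstream need score and
information at arbitrary parameter values and on nested snapshots of
the same trial; `lifelines` serves as an independent cross-check in the
test-suite and provides the Kaplan–Meier estimator. Newton–Raphson
starts at 0, demands a score max-norm below 1e-8, halves steps on a
likelihood decrease while far from the optimum, and takes the plain
Newton step once the score is below 1e-4 (near the optimum the
likelihood improvement is smaller than the float rounding of a
many-event log likelihood, so step-halving cannot discriminate).
Divergence of any coordinate beyond |β| = 10 is reported as a monotone
likelihood (an arm with events on one side only), never returned as an
estimate. Simulated event times are continuous, so ties have measure
zero and the Breslow approximation is exact in practice.

## Correlation structure of the arm-wise estimators

The shared control group correlates the arm-wise log-HR estimators;
near the null and with censoring independent of the arm the correlation
is √(p_k p_l)/√((p_0+p_k)(p_0+p_l)). Variances use the standard
1/d_k + 1/d_0 approximation in the observed event counts — justified
because only the total number of observed events matters for the
information of a log-HR — and simulation confirms the resulting
covariance blocks (unit tests at reduced replicates, the
acceptance suite at 10⁴ trials for the correlation). Across the two
stages the estimators follow the independent-increments joint normal:
Cov(β̂₁, β̂₂) = Cov(β̂₂, β̂₂) = Σ₂. The accuracy of the correlation
formula away from the null is assessed empirically, not assumed.

## Selection probabilities and conditional biases

With β̂₁ ~ N(β, Σ₁) and selection S = argmin_k β̂₁k, the selection
probability and the conditional bias of the selected arm are
one-dimensional integrals of (K−1)-dimensional normal orthant survivor
functions under the conditional law given β̂₁k = x. The dropped-arm
bias follows exactly from the law of total expectation,
cb⁻ = −cb⁺·P/(1−P), and is evaluated in the algebraically equivalent
form −num/(1−P) that stays finite when P underflows. The
final-analysis biases are linear combinations of the interim ones
through u_k = Σ₂ₖ·Σ₁⁻¹, with the v-vector built from cb1⁺ (own arm)
and cb1⁻ (other arms) exactly as the two-stage decomposition
prescribes; in the independent-arms case the stage ratio collapses to
the event-count ratio d₁/d₂. The decomposition conditions v_kl
(l ≠ k) on {S ≠ l} rather than on {S = k}; we implement it as printed
and verify it against a joint two-stage sampling oracle rather than
re-deriving the conditioning (acceptance suite, 10⁶ draws per model).

Numerics. The inner orthant survivor is a vectorized Genz
sequential-conditioning quasi-Monte-Carlo rule on scrambled Sobol
points with hard-coded seeds — deterministic, batched over all
quadrature nodes and arms at once, with an error estimate from
independent scramble replicates. The outer integral is adaptive: the
range β_k ± 8.5 σ starts as four panels, each panel carries an embedded
Gauss–Legendre 16/32 error estimate, and panels failing their
width-proportional share of the tolerance are bisected (depth cap 22).
Adaptivity matters: a nearly degenerate coordinate (e.g. a threshold
rule expressed as a pinned arm with σ → 0) turns the integrand into a
near-step that no fixed-order rule resolves. Presets: `ACCURATE`
(4 × 2¹⁵ Sobol points, tolerance 1e-6 — also the tolerance of the
sum-to-one invariant; tighter targets are not attainable for ≥3-dim
orthants at deterministic cost) and `FAST` (fixed-order 32-node outer
rule, 2⁸ points, absolute error ~1e-4) for use inside simulation loops
and the Stallard–Todd iteration, where the bias evaluation error is far
below the sampling noise of any estimate.

The lower bound on the unconditional selection bias, E[min of the
centred estimator vector], is computed as Σ_k E[(β̂_k−β_k)1{S=k}] with
the same machinery (closed forms for K ≤ 2); by Slepian's inequality it
is farthest from zero at zero correlation, which the tests check on a
correlation grid.

## Estimators

**Increment estimator.** δ̂ for an arm uses the score process of the
*restricted* two-arm (control + arm) Cox model, evaluated at the
restricted stage-1 MLE where the stage-1 score vanishes:
δ̂ = β̃₁ + (U₂ − U₁)/(I₂ − I₁). The restriction is deliberate: the
joint K-arm score's off-diagonal information would mix the other arms'
stage-1 noise into the increment (measured correlation ~0.3 with the
stage-1 estimate in a K=2 null design, versus ~0.01 for the restricted
form). By independent increments of the score the result is
asymptotically unbiased and independent of the stage-1 estimate given
the selection. Two-stage combinations are w·(stage-1 estimate) +
(1−w)·δ̂ with w defaulting to the information fraction d₁/d₂ of total
event counts, for the MLE, both shrinkage estimators and
Stallard–Todd alike.

**EB shrinkage.** Independent N(μ, τ²) priors on the per-arm log-HRs
with μ estimated by the pooled log-HR β̄ (all treatment arms merged,
one-covariate Cox fit) give the posterior-mean form
Ĉβ̂ + (I−Ĉ)β̄·1 with Ĉ = I − Σ̂(τ̂²I + Σ̂)⁻¹. τ̂² comes from the
Morris iteration applied to the orthogonal transform Û that
diagonalizes Σ̂: the transformed residuals Û(β̂ − β̄·1) are independent
with variances τ² + D_kk. Two readings of the printed weights were
possible (D_kk as a standard deviation or a variance); the eigenvalues
of a covariance matrix are variances, so the variance reading is used
and validated by parameter recovery (mean τ̂² within ~4% of a true
τ² = 0.04 at K = 6 and 100 events per arm, with the prior mean held at
its true value so that mean estimation does not confound the check).
Residuals are deviations from the transformed prior-mean term because
μ is replaced by β̄, not by the mean of the transformed components.
Convergence: |Δτ̂²| < 1e-10, at most 200 iterations, negative iterates
truncated to zero (τ̂² = 0 collapses every estimate onto β̄).

**LR shrinkage.** Scalar factor max(1 − m/Z, 0) toward β̄, with Z the
treatment-only score statistic (control excluded, lowest treatment arm
as baseline; χ²_{K−1} under equal effects) and m = K−3, replaced by
K−1 when K < 4; Z = 0 means full shrinkage, not an error. Pairwise
differences scale by the factor, so the ranking of arms never changes.

**Stallard–Todd.** The fixed point β̃ = β̂₁ − b(β̃), where b maps a
candidate truth to the conditional-bias vector under Σ̂₁ (selected arm:
given selection; others: given dropping), iterated from the MLE.
Convergence is declared when the residual max-norm is below 1e-6 and
the iterate whose residual was measured is returned, so the contract
holds exactly. Fallback to the MLE (flagged and counted, never an
error) on: any coordinate beyond 10, residuals increasing on five
consecutive iterations, or 100 iterations. The non-convergent cases
observed in practice are slow sub-geometric contractions, not true
divergence; the measured fallback rate in the two-arm null design is
~13–15%. No final-analysis fixed point is offered — only the marginal
covariance enters the bias formulas but only the conditional one is
estimable at stage 2, and the iteration diverges there — the two-stage
combination of the interim solution takes its place.

**Bias-corrected Kaplan–Meier.** The control-arm product-limit curve is
asymptotically unaffected by the selection, so the selected arm's curve
is reported as S₀(s)^exp(β̂*) for any bias-corrected β̂*, truncated at
the analysis horizon. The power relationship is applied on the survival
scale.

## Simulator

The defaults are the reference trial conditions: per-group cap 200
patients, equal allocation, exponential event times with baseline
hazard log 2 / 12 (12-month control median), interim after (K+1)·50
events across all arms, final after 200 events in control plus the
selected arm, follow-up of dropped arms continuing. Accrual is a
homogeneous arrival process calibrated so the full capacity
(K+1)·200 arrives in 24 months — the simplest staggered-entry law that
produces overrunning patients; the rate is a config knob. There is no
loss to follow-up by default (a censoring hook accepts any sampler);
administrative censoring happens only inside snapshots. After the
interim, allocation renormalizes over control and the selected arm
preserving their ratio, with per-group caps enforced sequentially and
patients who find all open arms full simply not recruited. Unit
exponential draws are stored per patient so that re-assigning an arm
only rescales the event time — stage-2 reassignment costs no extra
randomness and the whole trial is reproducible from one seed
(per-purpose substreams are spawned deterministically). Scenario
vectors: `constant` (all HR 1), `linear` (1 down to 0.6 in equal
steps), `peak` (one arm at 0.6).

What the generator does *not* emulate: non-exponential baselines,
non-proportional hazards, dropout, more than two stages, covariates
beyond the treatment indicators. Passing tests therefore demonstrate
correctness of the estimation machinery under the asymptotic normal
approximation it is built on, not robustness to violations of that
approximation.

## Conditional bootstrap

Patients (id, arm, entry, observed time, status) are resampled with
replacement from the final dataset; arm sizes therefore vary across
resamples. Each resample's interim is placed at its own calendar time
of event number round(f · d₂*), where f = d₁/d₂ is the original
information fraction and d₂* the resample's final event count — the
"same information fraction" rule made operational. The full snapshot
rule is applied at that time, which recensors overrunning patients and
subsumes the narrower reading of recensoring only them. A resample is
retained only when the originally selected arm again attains the
minimum stage-1 estimate; the requested estimator is evaluated on
retained resamples and plain percentile intervals are reported (the
method is explicitly approximate — conditioning cannot recover the
selection variability, and measured coverage of nominal 95% intervals
is ~0.89 in the two-arm null design). Note that the retention rate is
*not* the fresh-trial selection probability 1/K: the resample's
stage-1 estimate centres on the original data's estimate with
bootstrap noise of comparable size, so the original winner is
re-selected with probability ≈ 1/2 + arcsin(1/√2)/π ≈ 0.75 for K = 2
(measured 0.74).

## Study harness

One row per (scenario, K, allocation ratio, method, stage) with bias,
RMSE, Monte-Carlo standard errors, exclusion counts and the
Stallard–Todd fallback rate. The MSE is the prediction form
E[(β̂_S − β_S)²] — β_S is the true effect of the *randomly selected*
arm; the alternative error-about-E[β_S] is available behind the
`mse_of_mean` flag. Default 2000 replicates: the sign and ordering
patterns of interest (direction of the interim bias, shrinkage
improving bias and RMSE in the all-null scenario, the MLE winning in
the one-good-arm scenario, allocation-ratio correlations) are stable at
that size with the reported Monte-Carlo errors, which is the study
scale this package targets; larger runs are a config field away.
Replicates draw child seeds from a fixed spawn tree, so cells are
independently reproducible and the loop could be parallelized without
changing results; execution is serial. Figure-style magnitudes are
deliberately not asserted anywhere — only signs, orderings and the
event-ratio law.

## Known limitations

- All bias formulas live on the asymptotic normal approximation of the
  log-HR estimators; with fewer than ~25 events per group the
  finite-sample bias of the Cox MLE rivals the selection bias.
- The correlation formula is a null approximation; under strong
  effects the true correlation drifts from it (checked empirically).
- Confidence intervals with guaranteed coverage after selection are an
  open problem; the conditional bootstrap is a comparative tool, not a
  coverage guarantee.
- Selection rules other than "smallest estimated log-HR" would leave
  the shrinkage estimators unchanged but invalidate the printed bias
  formulas (min-specific) and hence the Stallard–Todd correction.
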