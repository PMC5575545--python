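# armselect

Estimation after treatment selection in two-stage multi-arm survival
trials.

## The problem

Multi-arm trials compare several experimental treatments against one
shared control group. In an adaptive two-stage design the
best-performing arm — the one with the *smallest* estimated log hazard
ratio (log-HR) at an event-driven interim analysis — continues to the
final analysis while recruitment to the other arms stops. Picking the
winner by its observed effect makes the usual Cox partial-likelihood
estimate of that effect too optimistic: the selected arm's log-HR is
biased downward (overestimated benefit) and the dropped arms' effects
are biased upward. Two features make the survival setting harder than
the normal-means one: the shared control group *correlates* the arm-wise
estimators (correlation ≈ √(p_k p_l)/√((p₀+p_k)(p₀+p_l)) for allocation
probabilities p), and the estimator variances depend on the random
numbers of observed events.

`armselect` provides, for trial statisticians and methodologists:

- Cox partial-likelihood machinery on **calendar-time snapshots**
  (staggered entry, administrative censoring, event-count-triggered
  analyses), written out so that score and information are available at
  arbitrary parameter values and on nested snapshots;
- the **selection probabilities and conditional selection biases** of
  the argmin of a correlated multivariate normal, at the interim and
  the final analysis, by deterministic adaptive quadrature;
- **bias-reduced point estimators**: empirical-Bayes (EB) shrinkage
  with a Morris-type fit of the prior variance, score-statistic (LR)
  shrinkage, the Stallard–Todd (ST) fixed point
  β̃ = β̂ − b(β̃) with MLE fallback, unbiased post-interim increment
  estimators and two-stage combinations
  w·β̂₁ + (1−w)·δ̂ with w the information fraction d₁/d₂;
- a **bias-corrected Kaplan–Meier** curve for the selected arm via the
  proportional-hazards power transform S_S = S₀^exp(β̂*);
- **conditional bootstrap** percentile intervals that condition on the
  original selection;
- a **trial simulator** and a **study harness** that quantify bias and
  RMSE of every method over scenario × K × allocation-ratio grids.

## Worked example

Simulate a three-arm trial with hazard ratios (1.0, 0.9, 0.8), a
control median survival of 12 months, interim analysis after
(K+1)·50 = 200 events and final analysis after 200 events in the
selected arm plus control, then apply every estimator:

```python
from armselect import DesignSpec, simulate_trial, build_context, estimate_all

design = DesignSpec(K=3, hazard_ratios=(1.0, 0.9, 0.8))
run = simulate_trial(design, seed=11)
print(run.interim_time, run.selected, run.final_time)
# 17.02 1 25.35

ctx = build_context(run.interim_fit, run.final_fit, run.selected)
for (method, stage), est in sorted(estimate_all(ctx).items()):
    print(f"{method:>3} {stage:<9}", round(est.for_arm(run.selected), 3))
#  EB final     -0.078
#  EB interim   -0.248
#  EB two_stage -0.026
#  LR final     -0.078
#  LR interim   -0.248
#  LR two_stage -0.026
# MLE final     -0.039
# MLE interim   -0.331
# MLE two_stage -0.07
#  ST interim   -0.109
#  ST two_stage 0.048
```

In this realization arm 1 happened to win at the interim with an
estimated log-HR of −0.33 although its true log-HR is 0 — exactly the
selection-bias situation. Every correction moves the interim estimate
toward the truth: EB/LR shrink it to −0.25, the Stallard–Todd fixed
point subtracts its model-predicted conditional bias to reach −0.11,
and the final-analysis MLE (−0.04), fed by the post-interim events, is
close to the truth by follow-up alone. The same analysis is available
from the shell:

```bash
armselect simulate --design design.yaml --seed 11 --out trial.csv
armselect estimate --trial trial.csv --design design.yaml
armselect bootstrap --trial trial.csv --design design.yaml \
    --method lr --stage two_stage --B 1000 --seed 3
armselect study --config study.yaml --out results.csv
```

where `design.yaml` mirrors `DesignSpec`, e.g. a five-arm design with
2:1:1:1:1 allocation, interim after 900 events and final analysis after
900 events in control plus the selected arm:

```yaml
K: 4
max_per_group: 450
allocation: [0.3333333333333333, 0.16666666666666666, 0.16666666666666666,
             0.16666666666666666, 0.16666666666666666]
interim_trigger: 900
final_trigger: 900
scenario: constant
```

A typical study table (`armselect study`, all-null scenario, K = 4,
2000 replicates — numbers produced by this code) shows the effect the
package exists to quantify: the selected-arm interim MLE is biased by
−0.155 while EB brings the bias to −0.020 and the RMSE from 0.238 to
0.166; at the final analysis the MLE bias has decayed to −0.073 by
continued follow-up alone.

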