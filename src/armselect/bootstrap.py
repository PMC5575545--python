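"""Conditional bootstrap confidence intervals.

After interim selection, naive bootstrap intervals are not available:
the selection in a resampled data set may differ from the original one,
but the decision to stop recruitment cannot be reversed retrospectively.
The conditional bootstrap therefore conditions on the original
selection ``S0``:

1. resample patients (with replacement) from the data accrued until the
   final analysis;
2. find the calendar time ``t*`` at which the resample reaches the
   *original information fraction* (the same fraction of its own final
   event count, not the same event count or calendar time);
3. build the stage-1 view of the resample, recensoring at ``t*`` every
   patient whose observed event falls after it;
4. compute the stage-1 MLEs;
5. keep the resample only if arm ``S0`` again attains the minimum, and
   evaluate the requested estimator on it.

Percentile intervals over the retained resamples are reported.  Because
the conditioning cannot reproduce the variability of the selection
itself, these intervals are approximate and expected to under-cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    ArmselectError,
    _trial_arrays,
    event_calendar_times,
    fit_cox,
    pooled_loghr,
    snapshot_arrays,
    treatment_only_statistic,
)
from .estimators import (
    REGISTRY,
    build_context,
    eb_shrinkage,
    lr_shrinkage,
    stallard_todd,
)
from .selection import FAST, Quadrature
from .simulate import TrialRun

__all__ = ["BootstrapResult", "conditional_bootstrap"]


@dataclass
class BootstrapResult:
    """Percentile interval of one estimator for the selected arm.

    ``lower <= point`` is *not* guaranteed — percentile intervals of a
    biased estimator need not cover its own point estimate.
    """

    method: str
    stage: str
    arm: int
    point: float
    lower: float
    upper: float
    level: float
    n_resamples_retained: int
    n_resamples_attempted: int
    n_fit_failures: int = 0
    estimates: pd.DataFrame | None = None

    @property
    def retention_rate(self) -> float:
        return self.n_resamples_retained / self.n_resamples_attempted


def _resample_estimate(
    method: str,
    stage: str,
    arm_rs, entry_rs, ev_rs, cens_rs,
    t_star: float,
    final_time: float,
    K: int,
    s0: int,
    weight: float | None,
    quadrature: Quadrature,
):
    """Stage-1 fit, retention check and estimator value for one
    resample; returns (retained, value)."""
    snap1 = snapshot_arrays(arm_rs, entry_rs, ev_rs, cens_rs, t_star)
    fit1 = fit_cox(snap1, arms=range(K + 1), baseline_arm=0)
    if fit1.arms[int(np.argmin(fit1.beta_hat))] != s0:
        return False, math.nan
    idx = fit1.arms.index(s0)
    if stage == "interim":
        if method == "MLE":
            return True, float(fit1.beta_hat[idx])
        if method == "EB":
            return True, eb_shrinkage(fit1, pooled_loghr(snap1)).for_arm(s0)
        if method == "LR":
            est = lr_shrinkage(
                fit1, pooled_loghr(snap1), treatment_only_statistic(snap1)
            )
            return True, est.for_arm(s0)
        if method == "ST":
            return True, stallard_todd(fit1, s0, quadrature=quadrature).for_arm(s0)
        raise ValueError(f"unknown method {method!r}")
    snap2 = snapshot_arrays(arm_rs, entry_rs, ev_rs, cens_rs, final_time)
    fit2 = fit_cox(snap2, arms=range(K + 1), baseline_arm=0)
    ctx = build_context(fit1, fit2, s0, weight=weight,
                        selection_quadrature=quadrature)
    fn = REGISTRY.get((method, stage))
    if fn is None:
        raise ValueError(f"estimator {method}/{stage} is not defined")
    return True, fn(ctx).for_arm(s0)


def conditional_bootstrap(
    trial: TrialRun,
    method: str = "MLE",
    stage: str = "interim",
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    weight: float | None = None,
    quadrature: Quadrature = FAST,
    return_estimates: bool = False,
) -> BootstrapResult:
    """Conditional-bootstrap percentile interval for the selected arm.

    ``B`` resamples are attempted; only those that re-select the
    original arm are retained.  The interim analysis of each resample
    happens at its own calendar time of the event whose rank matches
    the original information fraction ``d1/d2`` applied to the
    resample's final event count.

    Raises
    ------
    ArmselectError
        If no resample is retained (the error names the retention
        rate observed so far).
    ValueError
        If ``B < 1`` or the trial has no completed two-stage run.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if trial.final_fit is None or trial.final_time is None:
        raise ValueError("conditional bootstrap needs a completed two-stage run")
    rng = np.random.default_rng(seed)
    K = trial.design.K
    s0 = trial.selected

    # observed final data: follow-up and status at the final analysis,
    # paired with each patient's entry time
    _, arm_all, entry_all, ev_all, cens_all = _trial_arrays(trial.patients)
    rec = entry_all <= trial.final_time
    base = snapshot_arrays(
        arm_all[rec], entry_all[rec], ev_all[rec], cens_all[rec],
        trial.final_time,
    )
    arm0 = base.arm
    fup0 = base.followup
    stat0 = base.status.astype(bool)
    entry0 = entry_all[rec]
    n = arm0.shape[0]
    # observed rows as latent records: event at fup when status else
    # censoring at fup
    ev0 = np.where(stat0, fup0, np.inf)
    cens0 = np.where(stat0, np.inf, fup0)

    frac = trial.interim_fit.total_events / trial.final_fit.total_events

    # original point estimate
    ctx0 = build_context(trial.interim_fit, trial.final_fit, s0,
                         weight=weight, selection_quadrature=quadrature)
    fn = REGISTRY.get((method, stage))
    if fn is None:
        raise ValueError(f"estimator {method}/{stage} is not defined")
    point = fn(ctx0).for_arm(s0)

    values: list[float] = []
    rows: list[tuple[int, bool, float]] = []
    n_failures = 0
    for b in range(B):
        idx = rng.integers(0, n, n)
        arm_rs, entry_rs = arm0[idx], entry0[idx]
        ev_rs, cens_rs = ev0[idx], cens0[idx]
        ev_cal = event_calendar_times(arm_rs, entry_rs, ev_rs, cens_rs)
        d2_star = ev_cal.size
        if d2_star == 0:
            n_failures += 1
            continue
        target = min(max(int(round(frac * d2_star)), 1), d2_star)
        t_star = float(ev_cal[target - 1])
        try:
            retained, val = _resample_estimate(
                method, stage, arm_rs, entry_rs, ev_rs, cens_rs,
                t_star, trial.final_time, K, s0, weight, quadrature,
            )
        except ArmselectError:
            n_failures += 1
            continue
        if retained:
            values.append(val)
        if return_estimates:
            rows.append((b, retained, val if retained else math.nan))

    if not values:
        raise ArmselectError(
            f"no resample re-selected arm {s0}: 0/{B} retained "
            f"({n_failures} fit failures)"
        )
    values_arr = np.asarray(values)
    alpha = 1.0 - level
    lower, upper = np.quantile(values_arr, [alpha / 2, 1.0 - alpha / 2])
    return BootstrapResult(
        method=method,
        stage=stage,
        arm=s0,
        point=float(point),
        lower=float(lower),
        upper=float(upper),
        level=level,
        n_resamples_retained=len(values),
        n_resamples_attempted=B,
        n_fit_failures=n_failures,
        estimates=(
            pd.DataFrame(rows, columns=["resample", "retained", "estimate"])
            if return_estimates else None
        ),
    )
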