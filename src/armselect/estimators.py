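"""Point estimators of the selected (and dropped) arms' log-HRs.

Four families of estimators of the per-arm log hazard ratios after
interim selection of the best arm:

``MLE``
    The Cox partial-likelihood maximizer at the interim or final
    analysis, and the two-stage form ``w * b1_S + (1 - w) * delta_S``
    built from the post-interim increment of the score process.
``EB``
    Empirical-Bayes shrinkage toward the pooled log-HR with a
    matrix shrinkage factor ``C = I - Sigma (tau^2 I + Sigma)^{-1}``;
    the prior variance ``tau^2`` is fitted by the Morris iteration on
    the orthogonally transformed estimates.
``LR``
    Scalar shrinkage toward the pooled log-HR with factor
    ``max(1 - m/Z, 0)`` where ``Z`` is the treatment-only score
    statistic and ``m = K - 3`` (``K - 1`` when ``K < 4``).  Preserves
    the ordering of the components exactly.
``ST``
    The Stallard-Todd fixed point ``b_tilde = b_hat - bias(b_tilde)``,
    subtracting the model-predicted conditional selection biases at the
    candidate truth; falls back to the MLE when the iteration diverges.

The two-stage combination rule is shared by all families: stage-1
estimate and unbiased increment are mixed with the information-fraction
weight ``w = d1/d2``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .asymptotics import JointAsymptotics
from .core import (
    ArmselectError,
    CoxFit,
    StepFunction,
    fit_cox,
    pooled_loghr,
    score_info_at,
    treatment_only_statistic,
)
from .selection import (
    ACCURATE,
    FAST,
    Quadrature,
    SelectionModel,
    selection_bias_vector,
)

__all__ = [
    "TwoStageContext",
    "EstimateSet",
    "increment_estimator",
    "two_stage_combine",
    "eb_shrinkage",
    "lr_shrinkage",
    "stallard_todd",
    "km_bias_corrected",
    "build_context",
    "estimate_all",
    "METHODS",
    "STAGES",
    "REGISTRY",
]

MORRIS_TOL = 1e-10
MORRIS_MAX_ITER = 200

ST_RESIDUAL_TOL = 1e-6   # max-norm of the fixed-point residual
ST_MAX_ITER = 100
ST_DIVERGENCE = 10.0     # |beta| beyond this aborts the iteration
ST_OSCILLATION_WINDOW = 5  # consecutive residual increases -> fallback


class NoStageTwoInformationError(ArmselectError):
    """The information did not increase between the two analyses."""


@dataclass
class EstimateSet:
    """Per-arm point estimates of one method at one stage.

    ``estimates[i]`` belongs to arm ``arms[i]`` (the fit's arm order).
    ``shrinkage_factor`` is the scalar LR factor, the EB shrinkage
    matrix, or None; ``converged``/``fallback_used`` are meaningful for
    the Stallard-Todd method only.
    """

    method: str
    stage: str
    arms: list[int]
    estimates: np.ndarray
    shrinkage_factor: float | np.ndarray | None = None
    tau2: float | None = None
    converged: bool | None = None
    fallback_used: bool = False
    n_iter: int = 0

    def for_arm(self, arm: int) -> float:
        return float(self.estimates[self.arms.index(arm)])


@dataclass
class TwoStageContext:
    """Everything the estimator registry needs about one two-stage run.

    ``weight`` is the two-stage mixing weight ``w`` (defaults to the
    information fraction ``d1/d2``); ``increments[i]`` is the unbiased
    post-interim increment estimator of arm ``arms[i]`` (NaN where the
    arm-wise information did not increase).
    """

    fit1: CoxFit
    fit2: CoxFit
    selected: int
    weight: float
    pooled1: float
    pooled2: float
    z1: float
    z2: float
    increments: np.ndarray
    selection_quadrature: Quadrature = FAST
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def arms(self) -> list[int]:
        return self.fit1.arms

    @property
    def increment(self) -> float:
        """Increment estimator of the selected arm."""
        return float(self.increments[self.arms.index(self.selected)])


def increment_estimator(fit1: CoxFit, fit2: CoxFit, arm: int) -> float:
    """Unbiased increment estimator of one arm's log-HR from the
    post-interim gain of the score process.

    The joint treatment-indicator model is equivalent to K separate
    two-arm Cox models sharing the baseline, so the arm-specific score
    process is that of the restricted (control + arm) model; the joint
    fit's off-diagonal information would otherwise leak the other arms'
    stage-1 noise into the increment.  Both stages are evaluated at the
    common reference point ``beta = b1`` (the restricted stage-1 MLE),
    where the stage-1 score vanishes, giving the one-step form

        delta = b1 + (U2(b1) - U1(b1)) / (I2(b1) - I1(b1)),

    asymptotically independent of the stage-1 estimate given the
    selection (independent increments of the score).

    Raises
    ------
    NoStageTwoInformationError
        If the arm-wise observed information did not increase between
        the stages (e.g. the two fits saw identical data).
    """
    if arm not in fit1.arms or arm not in fit2.arms:
        raise ValueError(f"arm {arm} absent from a stage fit")
    if fit1.baseline_arm != fit2.baseline_arm:
        raise ValueError("stage fits must share the baseline arm")
    if fit1.snapshot is None or fit2.snapshot is None:
        raise ValueError("fits must carry their snapshots")
    base = fit1.baseline_arm
    pair = [base, arm]
    snap1 = fit1.snapshot.restrict(pair)
    snap2 = fit2.snapshot.restrict(pair)
    sub1 = fit_cox(snap1, arms=pair, baseline_arm=base)
    ref = sub1.beta_hat  # scalar reference: restricted stage-1 MLE
    U1, I1 = score_info_at(snap1, ref, arms=pair, baseline_arm=base)
    U2, I2 = score_info_at(snap2, ref, arms=pair, baseline_arm=base)
    dinfo = I2[0, 0] - I1[0, 0]
    if dinfo <= 0:
        raise NoStageTwoInformationError(
            f"arm {arm}: information did not increase after the interim "
            f"analysis (increment {dinfo:.3g})"
        )
    return float(ref[0] + (U2[0] - U1[0]) / dinfo)


def two_stage_combine(stage1_estimate: float, increment: float, w: float) -> float:
    """Weighted two-stage combination ``w * stage1 + (1 - w) * increment``.

    Applied identically whether ``stage1_estimate`` is the interim MLE,
    a shrinkage estimate or the Stallard-Todd estimate.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weight must lie in [0, 1], got {w}")
    return w * stage1_estimate + (1.0 - w) * increment


# ---------------------------------------------------------------------------
# Shrinkage
# ---------------------------------------------------------------------------

def _morris_tau2(resid: np.ndarray, variances: np.ndarray) -> tuple[float, int]:
    """Morris iteration for the prior variance ``tau^2``.

    ``resid`` are independent centred observations with variances
    ``tau^2 + variances[k]``; weights ``w_k = (tau^2 + D_k)^{-1}``
    re-estimate ``tau^2 = sum w_k (r_k^2 - D_k) / sum w_k``, truncated
    at zero, until the update is below ``MORRIS_TOL``.
    """
    tau2 = max(float(np.mean(resid**2 - variances)), 0.0)
    for it in range(1, MORRIS_MAX_ITER + 1):
        w = 1.0 / (tau2 + variances)
        new = float(np.sum(w * (resid**2 - variances)) / np.sum(w))
        new = max(new, 0.0)
        if abs(new - tau2) < MORRIS_TOL:
            return new, it
        tau2 = new
    raise ArmselectError(
        f"Morris iteration for tau^2 did not converge in {MORRIS_MAX_ITER} "
        f"iterations (last iterate {tau2:.6g})"
    )


def eb_shrinkage(fit: CoxFit, pooled: float, stage: str = "interim") -> EstimateSet:
    """Empirical-Bayes shrinkage of the log-HR vector toward the pooled
    log-HR.

    Independent ``N(mu, tau^2)`` priors on the true per-arm log-HRs
    with ``mu`` estimated by the pooled estimate give the posterior-mean
    form ``C b + (I - C) pooled`` with matrix shrinkage factor
    ``C = I - Sigma (tau^2 I + Sigma)^{-1}``.  ``tau^2`` is fitted by
    the Morris iteration applied to the orthogonal transform that
    diagonalizes the estimated covariance (the transformed residuals
    are independent with variances ``tau^2 + D_kk``).  ``tau^2 = 0``
    collapses every component onto the pooled estimate.
    """
    K = len(fit.arms)
    if K < 2:
        raise ValueError("EB shrinkage needs K >= 2 treatment arms")
    sigma = fit.cov_hat
    evals, evecs = np.linalg.eigh(sigma)
    if np.any(evals <= 0):
        raise ArmselectError("estimated covariance must be positive definite")
    U = evecs.T  # rows: eigenvectors; U sigma U' = diag(evals)
    resid = U @ (fit.beta_hat - pooled)
    tau2, n_iter = _morris_tau2(resid, evals)
    C = np.eye(K) - sigma @ np.linalg.inv(tau2 * np.eye(K) + sigma)
    est = C @ fit.beta_hat + (np.eye(K) - C) @ np.full(K, pooled)
    return EstimateSet(
        method="EB", stage=stage, arms=list(fit.arms), estimates=est,
        shrinkage_factor=C, tau2=tau2, n_iter=n_iter,
    )


def lr_shrinkage(fit: CoxFit, pooled: float, Z: float, K: int | None = None,
                 stage: str = "interim") -> EstimateSet:
    """Scalar shrinkage toward the pooled log-HR driven by the
    treatment-only score statistic ``Z`` (chi-square with K-1 df under
    equal effects): factor ``max(1 - m/Z, 0)`` with ``m = K - 3`` for
    ``K >= 4`` and ``K - 1`` otherwise.  ``Z = 0`` shrinks completely;
    pairwise differences (hence the ordering) of the estimates scale by
    the factor.
    """
    if Z < 0:
        raise ValueError("Z must be nonnegative")
    if K is None:
        K = len(fit.arms)
    m = K - 3 if K >= 4 else K - 1
    factor = max(1.0 - m / Z, 0.0) if Z > 0 else 0.0
    est = factor * fit.beta_hat + (1.0 - factor) * pooled
    return EstimateSet(
        method="LR", stage=stage, arms=list(fit.arms), estimates=est,
        shrinkage_factor=factor,
    )


# ---------------------------------------------------------------------------
# Stallard-Todd
# ---------------------------------------------------------------------------

def _default_model_builder(fit1: CoxFit) -> Callable[[np.ndarray], SelectionModel]:
    joint_cov = fit1.cov_hat
    base = SelectionModel(
        fit1.beta_hat, JointAsymptotics(fit1.beta_hat, joint_cov, joint_cov)
    )
    # with_beta shares the cached conditioning pieces (they depend only
    # on the covariance), so each fixed-point step costs one quadrature
    return base.with_beta


def stallard_todd(
    fit1: CoxFit,
    selected: int,
    model_builder: Callable[[np.ndarray], SelectionModel] | None = None,
    quadrature: Quadrature = ACCURATE,
) -> EstimateSet:
    """Stallard-Todd bias-corrected estimate at the interim analysis.

    Solves the fixed-point equation ``b_tilde = b_hat - bias(b_tilde)``
    where ``bias`` maps a candidate truth to the vector of conditional
    selection biases (selected arm: given selection; other arms: given
    being dropped) under the estimated interim covariance.  The
    iteration starts at the MLE; on divergence (coordinate beyond
    ``ST_DIVERGENCE``, residuals increasing over
    ``ST_OSCILLATION_WINDOW`` consecutive iterations, or the iteration
    budget) the MLE is returned with ``fallback_used`` set — the
    fallback is part of the contract, no error is raised.

    ``model_builder`` maps a candidate beta vector to the
    :class:`SelectionModel` used for the bias evaluation; the default
    uses the interim fit's estimated covariance for both stages.
    """
    if model_builder is None:
        model_builder = _default_model_builder(fit1)
    sel_idx = fit1.arms.index(selected)
    b_hat = fit1.beta_hat
    beta = b_hat.copy()
    prev_resid = math.inf
    n_increases = 0
    mle = EstimateSet(
        method="ST", stage="interim", arms=list(fit1.arms),
        estimates=b_hat.copy(), converged=False, fallback_used=True,
    )
    for n_iter in range(1, ST_MAX_ITER + 1):
        try:
            with warnings.catch_warnings():
                # intermediate iterates may pass through numerically
                # fragile regions (selection probability near 0/1); the
                # divergence rules below handle them
                warnings.simplefilter("ignore")
                bias = selection_bias_vector(
                    model_builder(beta), sel_idx, quadrature
                )
        except ArmselectError:
            mle.n_iter = n_iter
            return mle
        new = b_hat - bias
        resid = float(np.max(np.abs(new - beta)))
        if not np.all(np.isfinite(new)) or np.max(np.abs(new)) > ST_DIVERGENCE:
            mle.n_iter = n_iter
            return mle
        if resid > prev_resid:
            n_increases += 1
            if n_increases >= ST_OSCILLATION_WINDOW:
                mle.n_iter = n_iter
                return mle
        else:
            n_increases = 0
        if resid < ST_RESIDUAL_TOL:
            # return the iterate whose residual was actually measured,
            # so the convergence contract holds exactly
            return EstimateSet(
                method="ST", stage="interim", arms=list(fit1.arms),
                estimates=beta, converged=True, fallback_used=False,
                n_iter=n_iter,
            )
        beta = new
        prev_resid = resid
    mle.n_iter = ST_MAX_ITER
    return mle


# ---------------------------------------------------------------------------
# Bias-corrected Kaplan-Meier
# ---------------------------------------------------------------------------

def km_bias_corrected(
    control_km: StepFunction, beta_corrected: float, horizon: float
) -> StepFunction:
    """Survival curve of the selected arm implied by the control
    Kaplan-Meier curve and a (bias-corrected) log-HR: the proportional
    hazards power transform ``S_S(s) = S_0(s)^exp(beta)``, truncated at
    ``horizon``."""
    keep = control_km.x <= horizon
    power = math.exp(beta_corrected)
    return StepFunction(
        x=control_km.x[keep],
        y=control_km.y[keep] ** power,
        y0=control_km.y0**power,
    )


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

METHODS = ("MLE", "EB", "LR", "ST")
STAGES = ("interim", "final", "two_stage")


def build_context(
    fit1: CoxFit,
    fit2: CoxFit,
    selected: int,
    weight: float | None = None,
    selection_quadrature: Quadrature = FAST,
) -> TwoStageContext:
    """Assemble the shared inputs of all estimators for one trial run.

    ``weight`` defaults to the information fraction ``d1/d2`` (total
    events at interim over total events at the final analysis).
    Pooled log-HRs and treatment-only statistics are computed from the
    snapshots carried by the fits.
    """
    if weight is None:
        weight = fit1.total_events / fit2.total_events
    incr = np.full(len(fit1.arms), np.nan)
    for i, arm in enumerate(fit1.arms):
        try:
            incr[i] = increment_estimator(fit1, fit2, arm)
        except NoStageTwoInformationError:
            pass
    return TwoStageContext(
        fit1=fit1,
        fit2=fit2,
        selected=selected,
        weight=weight,
        pooled1=pooled_loghr(fit1.snapshot),
        pooled2=pooled_loghr(fit2.snapshot),
        z1=treatment_only_statistic(fit1.snapshot),
        z2=treatment_only_statistic(fit2.snapshot),
        increments=incr,
        selection_quadrature=selection_quadrature,
    )


def _two_stage_from(interim: EstimateSet, ctx: TwoStageContext) -> EstimateSet:
    est = np.array([
        two_stage_combine(interim.estimates[i], ctx.increments[i], ctx.weight)
        for i in range(len(interim.estimates))
    ])
    return EstimateSet(
        method=interim.method, stage="two_stage", arms=interim.arms,
        estimates=est, shrinkage_factor=interim.shrinkage_factor,
        tau2=interim.tau2, converged=interim.converged,
        fallback_used=interim.fallback_used,
    )


def _st_interim(ctx: TwoStageContext) -> EstimateSet:
    if "st_interim" not in ctx._cache:
        ctx._cache["st_interim"] = stallard_todd(
            ctx.fit1, ctx.selected, quadrature=ctx.selection_quadrature
        )
    return ctx._cache["st_interim"]


REGISTRY: dict[tuple[str, str], Callable[[TwoStageContext], EstimateSet]] = {
    ("MLE", "interim"): lambda ctx: EstimateSet(
        "MLE", "interim", list(ctx.arms), ctx.fit1.beta_hat.copy()
    ),
    ("MLE", "final"): lambda ctx: EstimateSet(
        "MLE", "final", list(ctx.arms), ctx.fit2.beta_hat.copy()
    ),
    ("MLE", "two_stage"): lambda ctx: _two_stage_from(
        EstimateSet("MLE", "interim", list(ctx.arms), ctx.fit1.beta_hat.copy()), ctx
    ),
    ("EB", "interim"): lambda ctx: eb_shrinkage(ctx.fit1, ctx.pooled1, "interim"),
    ("EB", "final"): lambda ctx: eb_shrinkage(ctx.fit2, ctx.pooled2, "final"),
    ("EB", "two_stage"): lambda ctx: _two_stage_from(
        eb_shrinkage(ctx.fit1, ctx.pooled1, "interim"), ctx
    ),
    ("LR", "interim"): lambda ctx: lr_shrinkage(
        ctx.fit1, ctx.pooled1, ctx.z1, stage="interim"
    ),
    ("LR", "final"): lambda ctx: lr_shrinkage(
        ctx.fit2, ctx.pooled2, ctx.z2, stage="final"
    ),
    ("LR", "two_stage"): lambda ctx: _two_stage_from(
        lr_shrinkage(ctx.fit1, ctx.pooled1, ctx.z1, stage="interim"), ctx
    ),
    ("ST", "interim"): _st_interim,
    # ST at the final analysis is deliberately absent: the fixed point
    # diverges there because only the conditional covariance given the
    # selection is estimable at stage 2.
    ("ST", "two_stage"): lambda ctx: _two_stage_from(_st_interim(ctx), ctx),
}


def estimate_all(
    ctx: TwoStageContext,
    methods: tuple[str, ...] = METHODS,
    stages: tuple[str, ...] = STAGES,
) -> dict[tuple[str, str], EstimateSet]:
    """Run every requested (method, stage) estimator on one context.

    Silently skips the undefined ST/final combination.
    """
    out: dict[tuple[str, str], EstimateSet] = {}
    for method in methods:
        for stage in stages:
            fn = REGISTRY.get((method, stage))
            if fn is None:
                continue
            out[(method, stage)] = fn(ctx)
    return out
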