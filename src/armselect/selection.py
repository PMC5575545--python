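"""Selection probabilities and conditional selection biases.

At the interim analysis the arm with the smallest estimated log hazard
ratio is selected.  Modelling the vector of interim estimators as
multivariate normal, ``b1 ~ N(beta, Sigma1)``, the probability of
selecting arm ``k`` and the conditional bias of its estimator given
selection (or given being dropped) are one-dimensional integrals of
multivariate-normal orthant survivor functions:

    P(S = k)  = int S_k(x) phi((x - beta_k)/s_k)/s_k dx,
    cb1k_plus = E[b1_k | S = k] - beta_k
              = int (x - beta_k) S_k(x) phi(.) dx / P(S = k),

where ``S_k(x)`` is the probability that every *other* coordinate
exceeds ``x`` under the conditional normal law given ``b1_k = x``.  The
dropped-arm bias follows from the law of total expectation,

    cb1k_minus = -cb1k_plus * P(S = k) / (1 - P(S = k)),

and the final-analysis biases are linear combinations of the interim
ones through the cross-stage covariance: with ``u_k`` the ``k``-th row
of ``Sigma2 Sigma1^{-1}``,

    cb2k_plus = sum_l u_kl v_kl,   v_kk = cb1k_plus, v_kl = cb1l_minus.

Numerics: the outer integral uses Gauss-Legendre on
``beta_k +/- 8.5 s_k`` (the integrand inherits the Gaussian envelope,
so a fixed high order is exact to well below the target tolerance); the
inner orthant survivor uses a vectorized Genz sequential-conditioning
quasi-Monte-Carlo rule on scrambled Sobol points with hard-coded seeds,
so every quantity here is deterministic.  The achieved inner error is
estimated from independent scramble replicates and reported through a
warning when it exceeds the requested tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

from .asymptotics import JointAsymptotics
from .core import ArmselectError

__all__ = [
    "SelectionModel",
    "ConditionalBias",
    "Quadrature",
    "ACCURATE",
    "FAST",
    "conditional_mvn",
    "selection_probability",
    "cb1_plus",
    "cb1_minus",
    "cb2_plus",
    "cb2_minus",
    "conditional_bias_table",
    "two_arm_threshold_bias",
    "bias_lower_bound",
    "orthant_survivor",
]

_SOBOL_SEED = 20170613  # fixed: makes the orthant integrator deterministic

_P_EXTREME = 1e-10  # warn when a selection probability is this close to 0/1


class DegenerateModelError(ArmselectError):
    """The covariance matrix does not admit the required conditioning."""


@dataclass(frozen=True)
class Quadrature:
    """Settings of the bias quadrature.

    ``outer_nodes`` Gauss-Legendre nodes on ``beta_k +/- tail * s_k``;
    the inner orthant survivor averages ``replicates`` scrambled-Sobol
    estimates of ``2**sobol_log2`` points each.  ``tol`` is the absolute
    tolerance against which the achieved-error estimate is checked.
    """

    outer_nodes: int = 128
    sobol_log2: int = 15
    replicates: int = 4
    tail: float = 8.5
    tol: float = 1e-6
    adaptive: bool = True


ACCURATE = Quadrature()
#: Reduced-accuracy preset used inside iterative/simulation loops
#: (Stallard-Todd fixed point, study harness); absolute error ~1e-4.
FAST = Quadrature(outer_nodes=32, sobol_log2=8, replicates=1, tol=1e-3,
                  adaptive=False)


@lru_cache(maxsize=64)
def _sobol_points(dim: int, log2: int, replicate: int) -> np.ndarray:
    eng = qmc.Sobol(d=dim, scramble=True, seed=_SOBOL_SEED + replicate)
    return eng.random_base2(m=log2)


@lru_cache(maxsize=16)
def _leggauss(n: int):
    return np.polynomial.legendre.leggauss(n)


def _genz_cdf(upper: np.ndarray, chol: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Batched MVN CDF ``P(Z < upper_b)`` for standardized ``Z``, by
    Genz sequential conditioning.

    ``upper`` has shape (B, d); ``chol`` is the lower Cholesky factor of
    the correlation matrix, either shared, shape (d, d), or per row,
    shape (B, d, d); ``points`` has shape (N, d-1) with entries in
    [0, 1).  Returns shape (B,).
    """
    B, d = upper.shape
    if chol.ndim == 2:
        chol = np.broadcast_to(chol, (B, d, d))
    if d == 1:
        return ndtr(upper[:, 0] / chol[:, 0, 0])
    N = points.shape[0]
    eps = 1e-15
    e = ndtr(upper[:, 0] / chol[:, 0, 0])[:, None]  # (B, 1)
    f = np.broadcast_to(e, (B, N)).copy()
    y = np.empty((d - 1, B, N))
    y[0] = ndtri(np.clip(points[None, :, 0] * e, eps, 1 - eps))
    for i in range(1, d):
        num = upper[:, i][:, None] - np.einsum(
            "bj,jbn->bn", chol[:, i, :i], y[:i]
        )
        e_i = ndtr(num / chol[:, i, i][:, None])
        f *= e_i
        if i < d - 1:
            y[i] = ndtri(np.clip(points[None, :, i] * e_i, eps, 1 - eps))
    return f.mean(axis=1)


def orthant_survivor(
    lower: np.ndarray,
    mean: np.ndarray,
    cov: np.ndarray,
    quadrature: Quadrature = ACCURATE,
    return_se: bool = False,
):
    """``P(X_i > lower_i for all i)`` for ``X ~ N(mean, cov)``, batched.

    ``lower`` may be (d,) or (B, d); ``mean`` broadcasts against it.
    Deterministic: the scrambled-Sobol point sets have fixed seeds.
    """
    lower = np.atleast_2d(np.asarray(lower, dtype=float))
    mean = np.broadcast_to(np.asarray(mean, dtype=float), lower.shape)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    d = cov.shape[0]
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        raise DegenerateModelError("orthant survivor needs positive variances")
    # P(X > l) = P(Z < u), Z standardized -(X - mean)
    upper = (mean - lower) / sd
    corr = cov / np.outer(sd, sd)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise DegenerateModelError("covariance matrix is not positive definite")
    if d == 1:
        est = ndtr(upper[:, 0])
        return (est, np.zeros_like(est)) if return_se else est
    reps = [
        _genz_cdf(upper, chol, _sobol_points(d - 1, quadrature.sobol_log2, r))
        for r in range(quadrature.replicates)
    ]
    reps = np.asarray(reps)
    est = reps.mean(axis=0)
    if return_se:
        if reps.shape[0] > 1:
            se = reps.std(axis=0, ddof=1) / math.sqrt(reps.shape[0])
        else:
            se = np.full_like(est, np.nan)
        return est, se
    return est


class SelectionModel:
    """True log-HRs plus the joint asymptotics of their estimators.

    Caches the Gaussian-conditioning pieces per coordinate so repeated
    bias evaluations (fixed-point iterations, studies) stay cheap.
    """

    def __init__(self, beta: np.ndarray, joint: JointAsymptotics):
        self.beta = np.asarray(beta, dtype=float)
        self.joint = joint
        if self.beta.shape[0] != joint.K:
            raise ValueError("beta dimension inconsistent with the joint asymptotics")
        self.sigma1 = joint.sigma1
        sign, logdet = np.linalg.slogdet(self.sigma1)
        if sign <= 0 or not np.isfinite(logdet):
            raise DegenerateModelError("Sigma1 must be positive definite")
        self._cond_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @property
    def K(self) -> int:
        return int(self.beta.shape[0])

    def _cond_parts(self, k: int):
        """Conditioning pieces for the remaining coordinates given
        coordinate ``k``: index vector, regression slope, conditional
        covariance, its standard deviations and the Cholesky factor of
        its correlation matrix.  All are independent of ``beta``, so
        they are shared by :meth:`with_beta` copies."""
        if k not in self._cond_cache:
            idx = [i for i in range(self.K) if i != k]
            s_kk = self.sigma1[k, k]
            s_rk = self.sigma1[idx, k]
            slope = s_rk / s_kk
            cov = self.sigma1[np.ix_(idx, idx)] - np.outer(s_rk, s_rk) / s_kk
            if cov.size:
                sd = np.sqrt(np.diag(cov))
                if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
                    raise DegenerateModelError(
                        "conditional covariance is singular; Sigma1 must be "
                        "positive definite"
                    )
                corr = cov / np.outer(sd, sd)
                try:
                    chol = np.linalg.cholesky(corr)
                except np.linalg.LinAlgError:
                    raise DegenerateModelError(
                        "conditional correlation matrix not positive definite"
                    )
            else:
                sd = np.empty(0)
                chol = np.empty((0, 0))
            self._cond_cache[k] = (np.asarray(idx), slope, cov, sd, chol)
        return self._cond_cache[k]

    def with_beta(self, beta: np.ndarray) -> "SelectionModel":
        """Copy with a different mean vector, sharing the cached
        (beta-independent) conditioning pieces — the workhorse of the
        Stallard-Todd fixed-point iteration."""
        m = object.__new__(SelectionModel)
        m.beta = np.asarray(beta, dtype=float)
        m.joint = self.joint
        m.sigma1 = self.sigma1
        m._cond_cache = self._cond_cache
        return m


def conditional_mvn(model: SelectionModel, k: int, x: float):
    """Mean and covariance of the other coordinates given
    ``b1_k = x`` (standard Gaussian conditioning)."""
    idx, slope, cov, _, _ = model._cond_parts(k)
    mean = model.beta[idx] + slope * (x - model.beta[k])
    return mean, cov


_PANEL_LO = 16   # embedded low order for the panel error estimate
_PANEL_HI = 32   # per-panel Gauss-Legendre order
_MAX_DEPTH = 22  # bisection depth cap of the adaptive outer integral
_MAX_ROUNDS = 40


def _survivor_values(model: SelectionModel, k_of_row: np.ndarray,
                     x_of_row: np.ndarray, quadrature: Quadrature):
    """Orthant survivor ``P(b_{-k} > x | b_k = x)`` for a batch of
    (arm, abscissa) rows, plus a per-row QMC standard-error estimate."""
    K = model.K
    n = x_of_row.shape[0]
    if K == 1:
        return np.ones(n), np.zeros(n)
    d = K - 1
    upper = np.empty((n, d))
    chol_rows = np.empty((n, d, d))
    for k in np.unique(k_of_row):
        mask = k_of_row == k
        idx, slope, _, sd, chol = model._cond_parts(int(k))
        x = x_of_row[mask]
        means = model.beta[idx][None, :] + slope[None, :] * (
            x - model.beta[int(k)]
        )[:, None]
        # P(others > x) = P(Z < (mean - x)/sd) standardized
        upper[mask] = (means - x[:, None]) / sd[None, :]
        chol_rows[mask] = chol
    if d == 1:
        return ndtr(upper[:, 0]), np.zeros(n)
    reps = np.asarray([
        _genz_cdf(upper, chol_rows, _sobol_points(d, quadrature.sobol_log2, r))
        for r in range(quadrature.replicates)
    ])
    surv = reps.mean(axis=0)
    if reps.shape[0] > 1:
        se = reps.std(axis=0, ddof=1) / math.sqrt(reps.shape[0])
    else:
        se = np.zeros(n)
    return surv, se


def _bias_integrals_multi(model: SelectionModel, ks, quadrature: Quadrature):
    """Outer quadrature returning arrays
    ``(P(S=k), E[(b1_k - beta_k) 1{S=k}])`` for every arm in ``ks``.

    All arms (and, in the adaptive mode, all pending panels) share one
    batched orthant-survivor evaluation per refinement round.  The
    adaptive mode bisects panels whose embedded Gauss-Legendre error
    estimate exceeds the width-proportional share of the tolerance —
    needed when the integrand has sharp features (e.g. a nearly
    degenerate coordinate pinned at a threshold).
    """
    ks = list(ks)
    K = model.K
    sig = np.array([math.sqrt(model.sigma1[k, k]) for k in ks])
    beta_k = model.beta[np.asarray(ks, dtype=int)] if K > 0 else np.empty(0)

    def dens(j, x):
        z = (x - beta_k[j]) / sig[j]
        return np.exp(-0.5 * z * z) / (math.sqrt(2 * math.pi) * sig[j])

    P = np.zeros(len(ks))
    num = np.zeros(len(ks))
    err = np.zeros(len(ks))

    if not quadrature.adaptive:
        nodes, weights = _leggauss(quadrature.outer_nodes)
        n_nodes = nodes.shape[0]
        k_rows = np.repeat(np.asarray(ks, dtype=int), n_nodes)
        j_rows = np.repeat(np.arange(len(ks)), n_nodes)
        half = quadrature.tail * sig
        x_rows = beta_k[j_rows] + half[j_rows] * np.tile(nodes, len(ks))
        w_rows = half[j_rows] * np.tile(weights, len(ks))
        surv, se = _survivor_values(model, k_rows, x_rows, quadrature)
        for j in range(len(ks)):
            m = j_rows == j
            g = surv[m] * dens(j, x_rows[m])
            P[j] = float(np.sum(w_rows[m] * g))
            num[j] = float(np.sum(w_rows[m] * (x_rows[m] - beta_k[j]) * g))
            err[j] = float(np.sum(np.abs(w_rows[m]) * se[m] * dens(j, x_rows[m])))
        _warn_errors(ks, err, quadrature)
        return P, num

    lo_nodes, lo_w = _leggauss(_PANEL_LO)
    hi_nodes, hi_w = _leggauss(_PANEL_HI)
    n_init = max(4, quadrature.outer_nodes // _PANEL_HI)
    pending: list[tuple[int, float, float, int]] = []
    for j in range(len(ks)):
        a = beta_k[j] - quadrature.tail * sig[j]
        b = beta_k[j] + quadrature.tail * sig[j]
        edges = np.linspace(a, b, n_init + 1)
        pending.extend(
            (j, float(edges[i]), float(edges[i + 1]), 0) for i in range(n_init)
        )

    block = _PANEL_LO + _PANEL_HI
    for _ in range(_MAX_ROUNDS):
        if not pending:
            break
        x_rows = np.empty(len(pending) * block)
        k_rows = np.empty(len(pending) * block, dtype=int)
        for p, (j, a, b, _depth) in enumerate(pending):
            mid, half = 0.5 * (a + b), 0.5 * (b - a)
            sl = slice(p * block, (p + 1) * block)
            x_rows[sl] = np.concatenate(
                [mid + half * lo_nodes, mid + half * hi_nodes]
            )
            k_rows[sl] = ks[j]
        surv, se = _survivor_values(model, k_rows, x_rows, quadrature)
        next_pending: list[tuple[int, float, float, int]] = []
        for p, (j, a, b, depth) in enumerate(pending):
            half = 0.5 * (b - a)
            sl_lo = slice(p * block, p * block + _PANEL_LO)
            sl_hi = slice(p * block + _PANEL_LO, (p + 1) * block)
            x_lo, x_hi = x_rows[sl_lo], x_rows[sl_hi]
            g_lo = surv[sl_lo] * dens(j, x_lo)
            g_hi = surv[sl_hi] * dens(j, x_hi)
            ip_lo = half * float(lo_w @ g_lo)
            ip_hi = half * float(hi_w @ g_hi)
            in_lo = half * float(lo_w @ ((x_lo - beta_k[j]) * g_lo))
            in_hi = half * float(hi_w @ ((x_hi - beta_k[j]) * g_hi))
            share = (b - a) / (2 * quadrature.tail * sig[j])
            e_p = abs(ip_hi - ip_lo)
            e_n = abs(in_hi - in_lo)
            ok = e_p <= quadrature.tol * share and (
                e_n <= quadrature.tol * sig[j] * share
            )
            if ok or depth >= _MAX_DEPTH:
                P[j] += ip_hi
                num[j] += in_hi
                err[j] += e_p + half * float(
                    np.abs(hi_w) @ (se[sl_hi] * dens(j, x_hi))
                )
            else:
                mid = 0.5 * (a + b)
                next_pending.append((j, a, mid, depth + 1))
                next_pending.append((j, mid, b, depth + 1))
        pending = next_pending
    else:
        # refinement budget exhausted: fold the remaining panels in at
        # their current accuracy
        for j, a, b, _depth in pending:
            half = 0.5 * (b - a)
            mid = 0.5 * (a + b)
            x_hi = mid + half * hi_nodes
            surv, se = _survivor_values(
                model, np.full(_PANEL_HI, ks[j], dtype=int), x_hi, quadrature
            )
            g_hi = surv * dens(j, x_hi)
            P[j] += half * float(hi_w @ g_hi)
            num[j] += half * float(hi_w @ ((x_hi - beta_k[j]) * g_hi))
            err[j] += quadrature.tol  # unknown; flag via the warning

    _warn_errors(ks, err, quadrature)
    return P, num


def _warn_errors(ks, err, quadrature: Quadrature) -> None:
    for j, k in enumerate(ks):
        if err[j] > quadrature.tol:
            warnings.warn(
                f"orthant quadrature for arm {k}: estimated absolute "
                f"error {err[j]:.2e} exceeds tolerance "
                f"{quadrature.tol:.0e}",
                stacklevel=4,
            )


def _bias_integrals(model: SelectionModel, k: int, quadrature: Quadrature):
    """``(P(S=k), E[(b1_k - beta_k) 1{S=k}])`` for a single arm."""
    P, num = _bias_integrals_multi(model, [k], quadrature)
    return float(P[0]), float(num[0])


def selection_probability(
    model: SelectionModel, k: int, quadrature: Quadrature = ACCURATE
) -> float:
    """Probability that arm ``k`` attains the smallest interim
    estimate.  The K probabilities sum to one (within quadrature
    tolerance)."""
    if model.K < 2:
        raise ValueError("selection needs K >= 2 arms")
    P, _ = _bias_integrals(model, k, quadrature)
    return P


def _checked_P(P: float, k: int) -> float:
    if P <= 0.0 or P >= 1.0:
        raise DegenerateModelError(
            f"selection probability of arm {k} is {P}; the conditional "
            "bias is undefined"
        )
    if P < _P_EXTREME or P > 1 - _P_EXTREME:
        warnings.warn(
            f"selection probability of arm {k} is {P:.3e}; conditional "
            "biases are numerically fragile",
            stacklevel=3,
        )
    return P


def cb1_plus(model: SelectionModel, k: int, quadrature: Quadrature = ACCURATE) -> float:
    """Interim conditional selection bias of arm ``k`` given it is
    selected, ``E[b1_k | S = k] - beta_k``; nonpositive when arms are
    exchangeable (the minimum undershoots)."""
    P, num = _bias_integrals(model, k, quadrature)
    return num / _checked_P(P, k)


def cb1_minus(model: SelectionModel, k: int, quadrature: Quadrature = ACCURATE) -> float:
    """Interim conditional bias of arm ``k`` given it is dropped; the
    exact counterweight ``-cb1_plus * P/(1 - P)`` of the selected-arm
    bias (law of total expectation)."""
    P, num = _bias_integrals(model, k, quadrature)
    P = _checked_P(P, k)
    return -(num / P) * P / (1.0 - P)


def _cb1_all(model: SelectionModel, quadrature: Quadrature):
    """Selection probabilities and both conditional biases of every arm
    in one quadrature pass.

    The dropped-arm bias is evaluated as ``-num/(1 - P)`` — identical to
    ``-cb1_plus * P/(1 - P)`` but stable when ``P`` underflows; the
    selected-arm bias ``num/P`` is NaN/inf for arms whose selection
    probability underflows (callers that expose it go through
    :func:`_checked_P`)."""
    P, num = _bias_integrals_multi(model, range(model.K), quadrature)
    with np.errstate(divide="ignore", invalid="ignore"):
        plus = num / P
    minus = -num / (1.0 - P)
    return P, plus, minus


def _u_row(model: SelectionModel, k: int) -> np.ndarray:
    # k-th row of Sigma2 Sigma1^{-1} (Sigma1 symmetric)
    return np.linalg.solve(model.sigma1, model.joint.sigma2[k])


def cb2_plus(model: SelectionModel, k: int, quadrature: Quadrature = ACCURATE) -> float:
    """Final-analysis conditional bias of the selected arm ``k``:
    ``sum_l u_kl v_kl`` with ``u_k`` the k-th row of
    ``Sigma2 Sigma1^{-1}`` and ``v`` built from the interim biases."""
    P, plus, minus = _cb1_all(model, quadrature)
    _checked_P(float(P[k]), k)
    v = minus.copy()
    v[k] = plus[k]
    return float(_u_row(model, k) @ v)


def cb2_minus(model: SelectionModel, k: int, quadrature: Quadrature = ACCURATE) -> float:
    """Final-analysis conditional bias of arm ``k`` given it was
    dropped: ``-cb2_plus * P/(1 - P)``."""
    P, plus, minus = _cb1_all(model, quadrature)
    _checked_P(float(P[k]), k)
    v = minus.copy()
    v[k] = plus[k]
    c2p = float(_u_row(model, k) @ v)
    return -c2p * float(P[k]) / (1.0 - float(P[k]))


@dataclass
class ConditionalBias:
    """Conditional biases of one arm at one stage."""

    arm: int
    stage: str  # "interim" or "final"
    selected_bias: float
    dropped_bias: float
    select_prob: float


def conditional_bias_table(
    model: SelectionModel, quadrature: Quadrature = ACCURATE
) -> list[ConditionalBias]:
    """All conditional biases of the model at both stages, sharing one
    pass of the interim quadrature."""
    P, plus, minus = _cb1_all(model, quadrature)
    for k in range(model.K):
        _checked_P(float(P[k]), k)
    out = [
        ConditionalBias(k, "interim", float(plus[k]), float(minus[k]), float(P[k]))
        for k in range(model.K)
    ]
    for k in range(model.K):
        v = minus.copy()
        v[k] = plus[k]
        c2p = float(_u_row(model, k) @ v)
        out.append(
            ConditionalBias(k, "final", c2p, -c2p * P[k] / (1.0 - P[k]), float(P[k]))
        )
    return out


def selection_bias_vector(
    model: SelectionModel, selected: int, quadrature: Quadrature = ACCURATE
) -> np.ndarray:
    """Interim bias vector ``b`` under the given truth: coordinate
    ``selected`` gets the selected-arm bias ``cb1_plus``, every other
    coordinate the dropped-arm bias ``cb1_minus``.  One shared
    quadrature pass over all arms (used by the Stallard-Todd fixed
    point).  Only the selected arm's selection probability must be
    bounded away from 0 and 1; near-zero probabilities of the dropped
    arms are harmless (their bias uses the stable form)."""
    P, plus, minus = _cb1_all(model, quadrature)
    _checked_P(float(P[selected]), selected)
    b = minus.copy()
    b[selected] = plus[selected]
    return b


def two_arm_threshold_bias(
    beta1: float, c: float, sigma_j1: float, sigma_11: float
) -> float:
    """Conditional bias in a two-arm trial stopped early for futility.

    When recruitment stops because the interim estimate exceeds a
    threshold ``c`` but follow-up continues, the stage-``j`` estimator
    of the single treatment arm has conditional bias

        (sigma_j1^2 / sigma_11) * phi(z) / (1 - Phi(z)),
        z = (c - beta1) / sigma_11,

    the inverse-Mills-ratio form of the truncated-normal mean.
    ``sigma_11`` is the interim standard deviation, ``sigma_j1`` the
    stage-``j`` one.
    """
    if sigma_11 <= 0:
        raise ValueError("sigma_11 must be positive")
    z = (c - beta1) / sigma_11
    dens = math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
    tail = ndtr(-z)  # 1 - Phi(z)
    if tail <= 0:
        return 0.0
    return (sigma_j1**2 / sigma_11) * dens / tail


def bias_lower_bound(
    joint: JointAsymptotics, stage: int, quadrature: Quadrature = ACCURATE
) -> float:
    """Lower bound ``E[min_k (b_k - beta_k)]`` of the selection bias at
    the given stage: the expected minimum of a centred multivariate
    normal with covariance ``Sigma_j``.  Attained when all true log-HRs
    are equal; increasing correlations move it toward zero (Slepian).
    """
    S = joint.sigma(stage)
    K = S.shape[0]
    if K == 1:
        return 0.0
    if K == 2:
        # E[min(X, Y)] = -sqrt(Var(X - Y) / (2 pi)) for a centred pair
        v = S[0, 0] + S[1, 1] - 2 * S[0, 1]
        return -math.sqrt(v / (2 * math.pi))
    centred = SelectionModel(np.zeros(K), JointAsymptotics(np.zeros(K), S, S))
    total = 0.0
    for k in range(K):
        _, num = _bias_integrals(centred, k, quadrature)
        total += num  # E[min] = sum_k E[(X_k - 0) 1{S=k}]
    return float(total)
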