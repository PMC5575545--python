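"""Asymptotic joint distribution of stage-wise log-HR estimators.

In a multi-arm trial with a shared control group the per-arm log hazard
ratio estimators are positively correlated: for stage-1 allocation
probabilities ``p_0, ..., p_K`` the correlation between the estimators
of arms ``k`` and ``l`` is approximately

    rho_kl = sqrt(p_k p_l) / sqrt((p_0 + p_k)(p_0 + p_l)),

valid near the null and with censoring independent of treatment.  The
per-arm variances are approximated by the standard ``1/d_k + 1/d_0``
rule in the observed event counts, and across the two analysis stages
the estimators follow a joint normal with covariance blocks

    Cov(b1, b1) = Sigma1,  Cov(b1, b2) = Cov(b2, b2) = Sigma2,

the independent-increments parameterization of group-sequential score
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AllocationSpec",
    "JointAsymptotics",
    "pairwise_correlation",
    "equal_allocation_correlation",
    "design_covariance",
]


@dataclass(frozen=True)
class AllocationSpec:
    """Stage-1 allocation probabilities ``(p_0, ..., p_K)``.

    ``p_0`` is the control allocation and must be positive; the vector
    must sum to one.
    """

    K: int
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(self.probs) != self.K + 1:
            raise ValueError(
                f"need K+1 = {self.K + 1} allocation probabilities, "
                f"got {len(self.probs)}"
            )
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0):
            raise ValueError("allocation probabilities must be nonnegative")
        if p[0] <= 0:
            raise ValueError("control allocation p_0 must be positive")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"allocation probabilities sum to {p.sum()}, not 1")

    @classmethod
    def from_ratio(cls, K: int, control: float, treatment: float) -> "AllocationSpec":
        """Allocation from a control:treatment ratio ``m:n`` with equal
        treatment arms, e.g. ``from_ratio(4, 3, 1)`` for 3:1."""
        total = control + K * treatment
        return cls(K=K, probs=tuple([control / total] + [treatment / total] * K))

    @classmethod
    def equal(cls, K: int) -> "AllocationSpec":
        return cls.from_ratio(K, 1.0, 1.0)

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


@dataclass
class JointAsymptotics:
    """Mean and stage covariance blocks of the joint MLE distribution.

    ``sigma1``/``sigma2`` are the marginal covariance matrices of the
    interim and final log-HR estimators; the cross-stage covariance
    block equals ``sigma2``.
    """

    beta: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma1 = np.asarray(self.sigma1, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        K = self.beta.shape[0]
        for name, s in (("sigma1", self.sigma1), ("sigma2", self.sigma2)):
            if s.shape != (K, K):
                raise ValueError(f"{name} must be {K}x{K}, got {s.shape}")
            if not np.allclose(s, s.T, atol=1e-12):
                raise ValueError(f"{name} must be symmetric")

    @property
    def K(self) -> int:
        return int(self.beta.shape[0])

    def sigma(self, stage: int) -> np.ndarray:
        if stage == 1:
            return self.sigma1
        if stage == 2:
            return self.sigma2
        raise ValueError("stage must be 1 or 2")

    def full_covariance(self) -> np.ndarray:
        """The 2K x 2K covariance of ``(b1, b2)`` with cross block
        ``sigma2`` (independent increments)."""
        K = self.K
        out = np.empty((2 * K, 2 * K))
        out[:K, :K] = self.sigma1
        out[:K, K:] = self.sigma2
        out[K:, :K] = self.sigma2
        out[K:, K:] = self.sigma2
        return out


def pairwise_correlation(alloc: AllocationSpec, k: int, l: int) -> float:
    """Correlation between the log-HR estimators of arms ``k`` and ``l``
    induced by the shared control group:
    ``sqrt(p_k p_l) / sqrt((p_0 + p_k)(p_0 + p_l))``.
    """
    if k == l:
        raise ValueError("pairwise correlation needs two distinct arms")
    if not (1 <= k <= alloc.K and 1 <= l <= alloc.K):
        raise ValueError(f"arms must be in 1..{alloc.K}, got {k}, {l}")
    p = alloc.p
    return float(
        np.sqrt(p[k] * p[l]) / np.sqrt((p[0] + p[k]) * (p[0] + p[l]))
    )


def equal_allocation_correlation(p0: float, K: int) -> float:
    """Common correlation under equal treatment allocation
    ``p_k = (1 - p0)/K``: ``(1 - p0) / (1 + (K - 1) p0)``."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1")
    return float((1.0 - p0) / (1.0 + (K - 1) * p0))


def design_covariance(
    alloc: AllocationSpec,
    events_stage1: np.ndarray,
    events_stage2: np.ndarray,
    beta: np.ndarray | None = None,
) -> JointAsymptotics:
    """Stage covariance blocks from per-arm event counts.

    Variances use the standard approximation ``1/d_jk + 1/d_j0``
    (treatment plus control events at stage ``j``); off-diagonals come
    from :func:`pairwise_correlation`.  Event counts must be positive
    and nondecreasing between stages.
    """
    K = alloc.K
    d1 = np.asarray(events_stage1, dtype=float)
    d2 = np.asarray(events_stage2, dtype=float)
    for name, d in (("events_stage1", d1), ("events_stage2", d2)):
        if d.shape != (K + 1,):
            raise ValueError(f"{name} must have length K+1 = {K + 1}")
        if np.any(d <= 0):
            raise ValueError(f"{name}: zero event counts make the design degenerate")
    if np.any(d2 < d1):
        raise ValueError("stage-2 event counts must be >= stage-1 counts")

    def block(d: np.ndarray) -> np.ndarray:
        var = 1.0 / d[1:] + 1.0 / d[0]
        sd = np.sqrt(var)
        S = np.empty((K, K))
        for k in range(1, K + 1):
            for l in range(1, K + 1):
                if k == l:
                    S[k - 1, l - 1] = var[k - 1]
                else:
                    rho = pairwise_correlation(alloc, k, l)
                    S[k - 1, l - 1] = rho * sd[k - 1] * sd[l - 1]
        return S

    if beta is None:
        beta = np.zeros(K)
    return JointAsymptotics(beta=np.asarray(beta, float), sigma1=block(d1), sigma2=block(d2))
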