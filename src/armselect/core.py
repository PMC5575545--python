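"""Cox partial-likelihood machinery for multi-arm survival trials.

This module provides the observable-data layer of an event-driven,
multi-arm trial: patient records carry *latent* event and censoring
times measured from each patient's entry into the trial, while a
:class:`Snapshot` holds what is actually observable at a calendar time
``t`` — the follow-up time ``Y_j(t) = min(T_j, C_j, t - R_j)`` and the
event indicator for every patient recruited by ``t``.  On top of the
snapshot sit the Cox proportional-hazards partial likelihood with
treatment-indicator covariates (score, information, Newton–Raphson
fit), the pooled-treatment log hazard ratio, the treatment-only score
statistic used by the LR shrinkage estimator, and the Kaplan–Meier
product-limit estimator.

The partial likelihood is written out explicitly rather than delegated
to a fitting library because downstream estimators need the score and
information evaluated at arbitrary parameter values (not only at the
MLE) and on nested snapshots of the same trial; lifelines is used as an
independent cross-check in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArmselectError",
    "NoEventsError",
    "NonConvergenceError",
    "MonotoneLikelihoodError",
    "InsufficientEventsError",
    "DegenerateStatisticError",
    "PatientRecord",
    "Snapshot",
    "CoxFit",
    "StepFunction",
    "snapshot",
    "calendar_time_of_event",
    "fit_cox",
    "score_info_at",
    "treatment_only_statistic",
    "pooled_loghr",
    "kaplan_meier",
    "read_patient_table",
    "write_patient_table",
]

# Newton-Raphson settings for the partial-likelihood maximization.
FIT_TOL = 1e-8          # max-norm of the score at the returned estimate
FIT_MAX_ITER = 50
BETA_DIVERGENCE = 10.0  # |beta| beyond this signals a monotone likelihood


class ArmselectError(Exception):
    """Base class for errors raised by armselect."""


class NoEventsError(ArmselectError):
    """The snapshot contains no events in the requested arms."""


class NonConvergenceError(ArmselectError):
    """Newton-Raphson failed to converge within the iteration budget."""


class MonotoneLikelihoodError(ArmselectError):
    """The partial likelihood is monotone (events on one side only)."""


class InsufficientEventsError(ArmselectError):
    """The trial never accrues the requested number of events."""


class DegenerateStatisticError(ArmselectError):
    """A score statistic could not be formed (singular information)."""


@dataclass(frozen=True)
class PatientRecord:
    """One subject of a multi-arm trial.

    Parameters
    ----------
    id : int
        Subject identifier.
    arm : int
        Treatment group, ``0`` is the common control.
    entry : float
        Calendar time of entry into the trial (months), ``>= 0``.
    event_time : float
        Latent survival time measured from entry, ``> 0``.  May be
        ``inf`` for a subject whose event was never observed (e.g. when
        reading an already-censored view of the data).
    censor_time : float
        Latent censoring time from entry, ``> 0``; defaults to ``inf``
        (no loss to follow-up — administrative censoring at an analysis
        is applied by :func:`snapshot`, not stored on the record).
    """

    id: int
    arm: int
    entry: float
    event_time: float
    censor_time: float = math.inf

    def __post_init__(self) -> None:
        if self.entry < 0:
            raise ValueError(f"entry must be >= 0, got {self.entry}")
        if not self.event_time > 0:
            raise ValueError(f"event_time must be > 0, got {self.event_time}")
        if not self.censor_time > 0:
            raise ValueError(f"censor_time must be > 0, got {self.censor_time}")
        if self.arm < 0:
            raise ValueError(f"arm must be a nonnegative integer, got {self.arm}")


@dataclass
class Snapshot:
    """Observable data ``D(t)`` of a trial at calendar time ``t``.

    Holds one row per patient recruited by ``analysis_time``: the
    treatment arm, the follow-up time ``Y_j(t)`` and the event status
    ``Delta_j(t)``.  Rows are stored as parallel numpy arrays.
    """

    analysis_time: float
    arm: np.ndarray      # int, shape (n_recruited,)
    followup: np.ndarray  # float, shape (n_recruited,)
    status: np.ndarray   # 0/1 int, shape (n_recruited,)
    ids: np.ndarray | None = None

    @property
    def n_recruited(self) -> int:
        return int(self.arm.shape[0])

    @property
    def rows(self) -> list[tuple[int, float, int]]:
        """Rows as ``(arm, followup, status)`` tuples."""
        return list(zip(self.arm.tolist(), self.followup.tolist(), self.status.tolist()))

    def events_per_arm(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for a in np.unique(self.arm):
            out[int(a)] = int(self.status[self.arm == a].sum())
        return out

    def restrict(self, arms: Iterable[int]) -> "Snapshot":
        """Snapshot restricted to patients in the given arms."""
        arms = set(int(a) for a in arms)
        mask = np.isin(self.arm, sorted(arms))
        return Snapshot(
            analysis_time=self.analysis_time,
            arm=self.arm[mask],
            followup=self.followup[mask],
            status=self.status[mask],
            ids=None if self.ids is None else self.ids[mask],
        )


@dataclass
class CoxFit:
    """A fitted Cox model with treatment-indicator covariates.

    ``beta_hat[i]`` is the log hazard ratio of ``arms[i]`` versus
    ``baseline_arm``; ``cov_hat`` is the inverse observed information at
    ``beta_hat``.  ``events_per_arm`` lists the event counts of
    ``groups = [baseline_arm] + arms`` in that order.
    """

    beta_hat: np.ndarray
    cov_hat: np.ndarray
    score: np.ndarray
    information: np.ndarray
    loglik: float
    events_per_arm: np.ndarray
    total_events: int
    baseline_arm: int
    arms: list[int]
    n_iter: int = 0
    snapshot: Snapshot | None = field(default=None, repr=False)

    @property
    def groups(self) -> list[int]:
        return [self.baseline_arm] + list(self.arms)


def _trial_arrays(trial: Sequence[PatientRecord]):
    n = len(trial)
    ids = np.empty(n, dtype=np.int64)
    arm = np.empty(n, dtype=np.int64)
    entry = np.empty(n, dtype=float)
    ev = np.empty(n, dtype=float)
    cens = np.empty(n, dtype=float)
    for i, p in enumerate(trial):
        ids[i] = p.id
        arm[i] = p.arm
        entry[i] = p.entry
        ev[i] = p.event_time
        cens[i] = p.censor_time
    return ids, arm, entry, ev, cens


def snapshot_arrays(
    arm: np.ndarray,
    entry: np.ndarray,
    event_time: np.ndarray,
    censor_time: np.ndarray,
    t: float,
    ids: np.ndarray | None = None,
) -> Snapshot:
    """Array-level form of :func:`snapshot` (used by the simulator and
    the bootstrap to avoid materializing record objects in hot loops)."""
    if t < 0:
        raise ValueError("analysis time must be >= 0")
    rec = entry <= t
    admin = t - entry[rec]  # administrative censoring time since entry
    # the event is on record iff it precedes censoring and its calendar
    # time is <= t; the calendar comparison uses entry + event_time so an
    # analysis scheduled exactly at an event time counts that event
    # (same float arithmetic as event_calendar_times)
    observed = (event_time[rec] <= censor_time[rec]) & (
        entry[rec] + event_time[rec] <= t
    )
    fup = np.where(
        observed,
        event_time[rec],
        np.minimum(censor_time[rec], admin),
    )
    status = observed.astype(np.int8)
    return Snapshot(
        analysis_time=float(t),
        arm=arm[rec],
        followup=fup,
        status=status,
        ids=None if ids is None else ids[rec],
    )


def snapshot(trial: Sequence[PatientRecord], t: float) -> Snapshot:
    """Observable data of ``trial`` at calendar time ``t``.

    Contains exactly the patients with ``entry <= t``; each contributes
    ``Y(t) = min(event_time, censor_time, t - entry)`` and the indicator
    of the event having occurred by then.  Patients whose event and
    censoring times both exceed ``t - entry`` are administratively
    censored at ``t - entry``.
    """
    ids, arm, entry, ev, cens = _trial_arrays(trial)
    return snapshot_arrays(arm, entry, ev, cens, t, ids=ids)


def event_calendar_times(
    arm: np.ndarray,
    entry: np.ndarray,
    event_time: np.ndarray,
    censor_time: np.ndarray,
    arms: Iterable[int] | None = None,
) -> np.ndarray:
    """Sorted calendar times at which events in ``arms`` are observed.

    An event is eventually observed iff it precedes the patient's
    censoring time; it then becomes visible at calendar time
    ``entry + event_time`` (a patient is always recruited before their
    own event, so no extra entry filter is needed).
    """
    mask = event_time <= censor_time
    if arms is not None:
        mask &= np.isin(arm, sorted(set(int(a) for a in arms)))
    return np.sort(entry[mask] + event_time[mask])


def calendar_time_of_event(
    trial: Sequence[PatientRecord],
    d: int,
    arms: Iterable[int] | None = None,
) -> float:
    """Smallest calendar time at which ``d`` events have been observed
    in the given arms (all arms when ``arms`` is None).

    Raises
    ------
    InsufficientEventsError
        If the trial never accrues ``d`` events in those arms.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    _, arm, entry, ev, cens = _trial_arrays(trial)
    times = event_calendar_times(arm, entry, ev, cens, arms)
    if times.size < d:
        raise InsufficientEventsError(
            f"trial accrues only {times.size} events in arms "
            f"{sorted(set(arm.tolist())) if arms is None else sorted(arms)}, "
            f"needed {d}"
        )
    return float(times[d - 1])


# ---------------------------------------------------------------------------
# Partial likelihood
# ---------------------------------------------------------------------------

def _group_codes(snap: Snapshot, arms: Iterable[int] | None, baseline_arm: int):
    """Map arm labels to group codes 0..G-1 with the baseline first.

    Returns ``(groups, code, followup, status)`` restricted to the
    requested arms.
    """
    present = set(int(a) for a in np.unique(snap.arm))
    if arms is None:
        arms_set = present
    else:
        arms_set = set(int(a) for a in arms)
    if baseline_arm not in arms_set:
        raise ValueError(f"baseline arm {baseline_arm} not in arms {sorted(arms_set)}")
    groups = [baseline_arm] + sorted(arms_set - {baseline_arm})
    lookup = {g: i for i, g in enumerate(groups)}
    mask = np.isin(snap.arm, groups)
    code = np.fromiter(
        (lookup[int(a)] for a in snap.arm[mask]), dtype=np.int64,
        count=int(mask.sum()),
    )
    return groups, code, snap.followup[mask], snap.status[mask]


def _plik_parts(times: np.ndarray, status: np.ndarray, code: np.ndarray, G: int):
    """Precompute the risk-set table shared by all beta evaluations.

    Returns ``(d_e, d_group, R, D)`` where for each distinct event time
    ``d_e`` is the number of events (Breslow tie handling), ``R[e, g]``
    the at-risk count of group ``g`` and ``D[g]`` the total events of
    group ``g``.
    """
    ev_mask = status == 1
    if not np.any(ev_mask):
        raise NoEventsError("snapshot has no events")
    te, inv = np.unique(times[ev_mask], return_inverse=True)
    E = te.shape[0]
    d_e = np.bincount(inv, minlength=E).astype(float)
    d_group = np.zeros((E, G))
    np.add.at(d_group, (inv, code[ev_mask]), 1.0)
    D = d_group.sum(axis=0)
    R = np.empty((E, G))
    for g in range(G):
        tg = np.sort(times[code == g])
        # at risk at te: followup >= te
        R[:, g] = tg.size - np.searchsorted(tg, te, side="left")
    return te, d_e, d_group, R, D


def _plik_score_info(beta_full: np.ndarray, d_e, R, D):
    """Log partial likelihood, score and information at ``beta_full``
    (length-G vector with the baseline entry fixed at 0)."""
    w = np.exp(beta_full)
    S1 = R * w  # (E, G)
    S0 = S1.sum(axis=1)
    p = S1 / S0[:, None]
    loglik = float(D @ beta_full - d_e @ np.log(S0))
    dp = p * d_e[:, None]
    U_full = D - dp.sum(axis=0)
    I_full = np.diag(dp.sum(axis=0)) - dp.T @ p
    return loglik, U_full[1:], I_full[1:, 1:]


def score_info_at(
    snap: Snapshot,
    beta: np.ndarray | Sequence[float] | float,
    arms: Iterable[int] | None = None,
    baseline_arm: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Score and observed information of the Cox partial likelihood at
    the supplied ``beta`` (not necessarily the MLE).

    ``beta[i]`` belongs to the i-th non-baseline arm in ascending
    label order.
    """
    groups, code, times, status = _group_codes(snap, arms, baseline_arm)
    G = len(groups)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.shape != (G - 1,):
        raise ValueError(f"beta must have length {G - 1}, got {beta.shape}")
    _, d_e, _, R, D = _plik_parts(times, status, code, G)
    beta_full = np.concatenate([[0.0], beta])
    _, U, I = _plik_score_info(beta_full, d_e, R, D)
    return U, I


def fit_cox(
    snap: Snapshot,
    arms: Iterable[int] | None = None,
    baseline_arm: int = 0,
    tol: float = FIT_TOL,
    max_iter: int = FIT_MAX_ITER,
) -> CoxFit:
    """Maximize the Breslow partial likelihood by Newton–Raphson.

    Treatment-indicator covariates relative to ``baseline_arm``,
    restricted to patients in ``arms`` (all arms present when None).
    Starts at 0, uses step-halving when a step decreases the likelihood
    and signals a monotone likelihood instead of returning divergent
    estimates.

    Raises
    ------
    NoEventsError
        If the restricted snapshot has no events.
    MonotoneLikelihoodError
        If some coordinate of the estimate diverges (an arm with events
        on one side only) or the information is singular.
    NonConvergenceError
        If the score does not vanish within ``max_iter`` iterations.
    """
    groups, code, times, status = _group_codes(snap, arms, baseline_arm)
    G = len(groups)
    _, d_e, _, R, D = _plik_parts(times, status, code, G)

    beta = np.zeros(G)  # full vector, baseline fixed at 0
    loglik, U, I = _plik_score_info(beta, d_e, R, D)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(U)) < tol:
            break
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            raise MonotoneLikelihoodError(
                "singular information matrix: an arm has no events or no "
                "at-risk patients on one side of a comparison"
            )
        if np.max(np.abs(U)) < 1e-4:
            # in the quadratic regime the Newton step is safe; the
            # likelihood change is below float noise of the total
            # loglik, so step-halving cannot discriminate
            beta[1:] += step
            loglik, U, I = _plik_score_info(beta, d_e, R, D)
        else:
            # step-halving on likelihood decrease
            scale = 1.0
            for _ in range(30):
                cand = beta.copy()
                cand[1:] += scale * step
                cand_ll, cand_U, cand_I = _plik_score_info(cand, d_e, R, D)
                if cand_ll >= loglik - 1e-12:
                    break
                scale *= 0.5
            beta, loglik, U, I = cand, cand_ll, cand_U, cand_I
        if np.max(np.abs(beta)) > BETA_DIVERGENCE:
            raise MonotoneLikelihoodError(
                f"estimate diverged beyond |beta| = {BETA_DIVERGENCE}: "
                "likely an arm with events only on one side"
            )
    else:
        raise NonConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(max |score| = {np.max(np.abs(U)):.3g})"
        )

    try:
        cov = np.linalg.inv(I)
    except np.linalg.LinAlgError:
        raise MonotoneLikelihoodError("information matrix singular at the MLE")
    return CoxFit(
        beta_hat=beta[1:].copy(),
        cov_hat=cov,
        score=U,
        information=I,
        loglik=loglik,
        events_per_arm=D.copy(),
        total_events=int(round(D.sum())),
        baseline_arm=baseline_arm,
        arms=groups[1:],
        n_iter=n_iter,
        snapshot=snap,
    )


def treatment_only_statistic(snap: Snapshot) -> float:
    """Score (log-rank) statistic for equality of the treatment arms.

    Compares arms ``1..K`` directly — the control group is excluded and
    the lowest-labelled treatment arm is the baseline — via
    ``U0' I0^{-1} U0`` with score and information evaluated at beta = 0.
    Asymptotically chi-square with K-1 degrees of freedom under equality
    of the treatment effects; used by the LR shrinkage estimator.
    """
    t_arms = sorted(int(a) for a in np.unique(snap.arm) if a != 0)
    if len(t_arms) < 2:
        raise DegenerateStatisticError(
            "treatment-only statistic needs >= 2 treatment arms"
        )
    sub = snap.restrict(t_arms)
    U0, I0 = score_info_at(sub, np.zeros(len(t_arms) - 1),
                           arms=t_arms, baseline_arm=t_arms[0])
    try:
        z = float(U0 @ np.linalg.solve(I0, U0))
    except np.linalg.LinAlgError:
        raise DegenerateStatisticError("singular information at beta = 0")
    return z


def pooled_loghr(snap: Snapshot) -> float:
    """Overall log hazard ratio: all treatment arms pooled vs control.

    Fits a single-covariate Cox model after merging every treatment
    group into one pseudo-arm.
    """
    pooled = Snapshot(
        analysis_time=snap.analysis_time,
        arm=(snap.arm > 0).astype(np.int64),
        followup=snap.followup,
        status=snap.status,
    )
    fit = fit_cox(pooled, arms=[0, 1], baseline_arm=0)
    return float(fit.beta_hat[0])


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class StepFunction:
    """Right-continuous step function ``t -> value``.

    ``y0`` is the value before the first jump at ``x[0]``; on
    ``[x[i], x[i+1])`` the value is ``y[i]``.
    """

    x: np.ndarray
    y: np.ndarray
    y0: float = 1.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.x, t, side="right") - 1
        out = np.where(idx < 0, self.y0, self.y[np.clip(idx, 0, len(self.y) - 1)])
        return float(out) if out.ndim == 0 else out

    @property
    def domain_end(self) -> float:
        return float(self.x[-1]) if self.x.size else 0.0


def kaplan_meier(snap: Snapshot, arm: int) -> StepFunction:
    """Kaplan–Meier product-limit estimator of the survival function in
    one arm of the snapshot (via lifelines)."""
    from lifelines import KaplanMeierFitter

    mask = snap.arm == arm
    if not np.any(mask):
        raise ValueError(f"arm {arm} has no patients in the snapshot")
    if snap.status[mask].sum() == 0:
        # no events: survival identically 1 up to the last follow-up
        last = float(snap.followup[mask].max())
        return StepFunction(x=np.array([last]), y=np.array([1.0]), y0=1.0)
    kmf = KaplanMeierFitter()
    kmf.fit(snap.followup[mask], event_observed=snap.status[mask])
    sf = kmf.survival_function_
    x = sf.index.to_numpy(dtype=float)
    y = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = x > 0
    return StepFunction(x=x[keep], y=y[keep], y0=1.0)


# ---------------------------------------------------------------------------
# Patient tables on disk
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["id", "arm", "entry", "time", "status"]


def write_patient_table(
    path: str | Path,
    trial: Sequence[PatientRecord],
    latent: bool = True,
    delimiter: str = ",",
) -> None:
    """Write a trial as a delimited table ``id, arm, entry, time, status``.

    With ``latent=True`` (the default, written by the simulator) the
    ``time`` column is the latent event time when the event precedes
    censoring (status 1) and the censoring time otherwise (status 0).
    A comment line records the view so the reader can recover it.
    """
    rows = []
    for p in trial:
        if math.isinf(p.event_time) and math.isinf(p.censor_time):
            raise ValueError(
                f"patient {p.id}: cannot serialize a record with neither an "
                "event nor a censoring time"
            )
        if p.event_time <= p.censor_time:
            time, status = p.event_time, 1
        else:
            time, status = p.censor_time, 0
        rows.append((p.id, p.arm, p.entry, time, status))
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    view = "latent" if latent else "snapshot"
    with open(path, "w") as fh:
        fh.write(f"# view={view}\n")
        df.to_csv(fh, sep=delimiter, index=False)


def read_patient_table(
    path: str | Path,
    latent: bool | None = None,
    delimiter: str = ",",
) -> list[PatientRecord]:
    """Read a delimited patient table into :class:`PatientRecord` rows.

    ``latent`` overrides the ``# view=`` comment written by
    :func:`write_patient_table`; both views map onto records the same
    way (status 1: event at ``time``; status 0: censored at ``time``,
    event time unknown), the flag documents whether ``time`` is a
    latent time or an already-snapshotted follow-up.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if latent is None and "view=" in first:
            latent = first.split("view=")[1].strip() == "latent"
    df = pd.read_csv(path, sep=delimiter, skiprows=skip)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient table {path} lacks columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        status = int(row.status)
        if status not in (0, 1):
            raise ValueError(f"patient {row.id}: status must be 0 or 1")
        records.append(
            PatientRecord(
                id=int(row.id),
                arm=int(row.arm),
                entry=float(row.entry),
                event_time=float(row.time) if status == 1 else math.inf,
                censor_time=float(row.time) if status == 0 else math.inf,
            )
        )
    return records
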