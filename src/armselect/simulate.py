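"""Simulation of two-stage multi-arm survival trials.

Patients enter the trial under staggered accrual (homogeneous arrival
process), are randomized to the control or one of ``K`` treatment arms,
and experience exponential event times with hazard
``lambda0 * HR_arm``.  The interim analysis is event-driven: it takes
place at the calendar time of the ``(K+1)*50``-th observed event (all
arms combined, by default), the arm with the smallest estimated log-HR
is selected, recruitment stops in the other treatment arms, and accrual
continues into the control and selected arms (preserving their
allocation ratio, up to the per-group cap).  The final analysis occurs
after a fixed number of events in the selected arm plus control;
follow-up of the dropped arms continues by default, so their estimates
keep maturing.

Three named hazard-ratio scenarios span the configurations usually
studied: ``constant`` (all HRs 1 — selection is pure noise and the
selection bias is maximal), ``linear`` (HRs from 1 down to 0.6) and
``peak`` (one active arm at HR 0.6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .asymptotics import AllocationSpec
from .core import (
    CoxFit,
    InsufficientEventsError,
    PatientRecord,
    Snapshot,
    event_calendar_times,
    fit_cox,
    snapshot_arrays,
)

__all__ = [
    "DesignSpec",
    "TrialRun",
    "scenario_hazards",
    "simulate_trial",
    "analyze_trial",
    "design_to_dict",
    "design_from_dict",
    "with_scenario",
]

DEFAULT_BASELINE_HAZARD = math.log(2) / 12  # median survival 12 months
DEFAULT_ACCRUAL_MONTHS = 24  # full capacity accrued over two years


def scenario_hazards(name: str, K: int) -> np.ndarray:
    """Hazard-ratio vector of a named scenario.

    ``constant``: all ones; ``linear``: equal steps of ``0.4/(K-1)``
    from 1 (arm 1) down to 0.6 (arm K); ``peak``: arm 1 at 0.6, the
    rest at 1.
    """
    if K < 2:
        raise ValueError("scenarios need K >= 2 treatment arms")
    name = name.lower()
    if name == "constant":
        return np.ones(K)
    if name == "linear":
        return 1.0 - 0.4 * np.arange(K) / (K - 1)
    if name == "peak":
        hr = np.ones(K)
        hr[0] = 0.6
        return hr
    raise ValueError(f"unknown scenario {name!r}; use constant, linear or peak")


@dataclass(frozen=True)
class DesignSpec:
    """Design of a two-stage multi-arm trial.

    Parameters
    ----------
    K : int
        Number of treatment arms (control is extra).
    max_per_group : int
        Recruitment cap per group (control and each treatment arm).
    allocation : AllocationSpec, optional
        Stage-1 allocation probabilities; equal by default.
    accrual_rate : float, optional
        Patients per month; defaults to the full capacity
        ``(K+1) * max_per_group`` accrued over 24 months.
    baseline_hazard : float
        Control-arm exponential hazard (per month).
    hazard_ratios : tuple of float
        True hazard ratio of each treatment arm vs control.
    interim_trigger : int
        Events across all arms that trigger the interim analysis;
        default ``(K+1) * 50``.
    final_trigger : int
        Events in the selected arm plus control that trigger the final
        analysis; default 200.
    followup_dropped : bool
        Whether dropped arms remain under follow-up (and in the final
        fit) after the interim analysis.
    censoring : callable, optional
        Hook drawing per-patient censoring times,
        ``censoring(rng, n) -> array``; None means no loss to follow-up
        (administrative censoring at analyses only).
    seed : int, optional
        Default seed used when :func:`simulate_trial` gets none.
    """

    K: int
    max_per_group: int = 200
    allocation: AllocationSpec | None = None
    accrual_rate: float | None = None
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD
    hazard_ratios: tuple[float, ...] | None = None
    interim_trigger: int | None = None
    final_trigger: int = 200
    followup_dropped: bool = True
    censoring: Callable[[np.random.Generator, int], np.ndarray] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.max_per_group < 1:
            raise ValueError("max_per_group must be >= 1")
        if self.allocation is None:
            object.__setattr__(self, "allocation", AllocationSpec.equal(self.K))
        if self.allocation.K != self.K:
            raise ValueError("allocation inconsistent with K")
        if self.hazard_ratios is None:
            object.__setattr__(self, "hazard_ratios", tuple([1.0] * self.K))
        hr = tuple(float(h) for h in self.hazard_ratios)
        if len(hr) != self.K or any(h <= 0 for h in hr):
            raise ValueError("hazard_ratios must be K positive numbers")
        object.__setattr__(self, "hazard_ratios", hr)
        if self.interim_trigger is None:
            object.__setattr__(self, "interim_trigger", (self.K + 1) * 50)
        if self.interim_trigger < 1 or self.final_trigger < 1:
            raise ValueError("event triggers must be >= 1")
        if self.accrual_rate is None:
            rate = (self.K + 1) * self.max_per_group / DEFAULT_ACCRUAL_MONTHS
            object.__setattr__(self, "accrual_rate", float(rate))
        if self.accrual_rate <= 0 or self.baseline_hazard <= 0:
            raise ValueError("accrual rate and baseline hazard must be positive")

    @property
    def capacity(self) -> int:
        return (self.K + 1) * self.max_per_group

    def log_hazard_ratios(self) -> np.ndarray:
        return np.log(np.asarray(self.hazard_ratios))


@dataclass
class TrialRun:
    """One realized two-stage trial."""

    design: DesignSpec
    patients: list[PatientRecord]
    interim_time: float
    selected: int
    interim_snapshot: Snapshot
    interim_fit: CoxFit
    final_time: float | None = None
    final_snapshot: Snapshot | None = None
    final_fit: CoxFit | None = None

    @property
    def snapshots(self) -> tuple[Snapshot, Snapshot | None]:
        return self.interim_snapshot, self.final_snapshot

    @property
    def fits(self) -> tuple[CoxFit, CoxFit | None]:
        return self.interim_fit, self.final_fit

    @property
    def true_selected_loghr(self) -> float:
        return float(math.log(self.design.hazard_ratios[self.selected - 1]))


def _capped_assign(arm: np.ndarray, counts: np.ndarray, caps: np.ndarray,
                   u: np.ndarray, probs: np.ndarray, arms: np.ndarray):
    """Sequentially re-draw assignments from the first cap violation on.

    ``arm`` is the tentative vectorized assignment (entries are values
    of ``arms``); ``counts`` are prior per-group totals.  Returns the
    corrected assignment with -1 marking patients who could not be
    recruited (all groups full).
    """
    arm = arm.copy()
    running = counts.copy()
    n = arm.shape[0]
    # fast path: find the first index where a cap is exceeded
    first_bad = n
    for a in arms:
        hits = np.flatnonzero(arm == a)
        if running[a] + hits.size > caps[a]:
            first_bad = min(first_bad, hits[caps[a] - running[a]])
    if first_bad == n:
        return arm
    for a in arms:
        running[a] += int(np.sum(arm[:first_bad] == a))
    for i in range(first_bad, n):
        open_arms = arms[running[arms] < caps[arms]]
        if open_arms.size == 0:
            arm[i:] = -1
            break
        p = probs[open_arms]
        p = p / p.sum()
        a = int(open_arms[np.searchsorted(np.cumsum(p), u[i], side="right")])
        arm[i] = a
        running[a] += 1
    return arm


def simulate_trial(
    design: DesignSpec,
    seed: int | None = None,
    interim_only: bool = False,
) -> TrialRun:
    """Simulate one two-stage trial under the design.

    Deterministic given ``seed`` (falls back to ``design.seed``).
    Raises :class:`InsufficientEventsError` (with the achieved counts)
    when the recruitment caps cannot feed an event trigger.
    """
    if seed is None:
        seed = design.seed
    if seed is None:
        raise ValueError("a seed is required (argument or design.seed)")
    rng = np.random.default_rng(seed)
    entries_rng, arms_rng, events_rng, censor_rng = rng.spawn(4)

    K = design.K
    N = design.capacity
    caps = np.full(K + 1, design.max_per_group)
    probs = design.allocation.p
    hr_full = np.concatenate([[1.0], np.asarray(design.hazard_ratios)])

    entry = np.cumsum(entries_rng.exponential(1.0 / design.accrual_rate, N))
    u_arm = arms_rng.random(N)
    arm = np.searchsorted(np.cumsum(probs), u_arm, side="right").astype(np.int64)
    arm = _capped_assign(arm, np.zeros(K + 1, dtype=int), caps, u_arm, probs,
                         np.arange(K + 1))
    recruited = arm >= 0
    # unit-exponential draws: reassigning an arm just rescales the time
    unit_exp = events_rng.exponential(1.0, N)
    if design.censoring is not None:
        censor = np.asarray(design.censoring(censor_rng, N), dtype=float)
    else:
        censor = np.full(N, np.inf)

    def times_for(a: np.ndarray) -> np.ndarray:
        safe = np.clip(a, 0, K)
        return unit_exp / (design.baseline_hazard * hr_full[safe])

    event_time = times_for(arm)

    def observed_events(mask: np.ndarray, arms_sel=None) -> np.ndarray:
        return event_calendar_times(
            arm[mask], entry[mask], event_time[mask], censor[mask], arms_sel
        )

    ev_times = observed_events(recruited)
    if ev_times.size < design.interim_trigger:
        raise InsufficientEventsError(
            f"interim trigger {design.interim_trigger} not reachable: only "
            f"{ev_times.size} events can ever be observed"
        )
    t1 = float(ev_times[design.interim_trigger - 1])

    snap1 = snapshot_arrays(
        arm[recruited], entry[recruited], event_time[recruited],
        censor[recruited], t1, ids=np.flatnonzero(recruited),
    )
    fit1 = fit_cox(snap1, arms=range(K + 1), baseline_arm=0)
    selected = int(fit1.arms[int(np.argmin(fit1.beta_hat))])

    if interim_only:
        keep = recruited & (entry <= t1)
        patients = [
            PatientRecord(int(i), int(arm[i]), float(entry[i]),
                          float(event_time[i]), float(censor[i]))
            for i in np.flatnonzero(keep)
        ]
        return TrialRun(
            design=design, patients=patients, interim_time=t1,
            selected=selected, interim_snapshot=snap1, interim_fit=fit1,
        )

    # Post-interim accrual: recruitment stops in the dropped arms and the
    # remaining allocation renormalizes over control + selected.
    post = entry > t1
    open_arms = np.array([0, selected])
    counts_stage1 = np.array([
        int(np.sum((arm == a) & ~post & recruited)) for a in range(K + 1)
    ])
    q = np.zeros(K + 1)
    q[0], q[selected] = probs[0], probs[selected]
    q = q / q.sum()
    u_post = arms_rng.random(int(post.sum()))
    tentative = np.where(u_post < q[0], 0, selected).astype(np.int64)
    arm_post = _capped_assign(tentative, counts_stage1, caps, u_post, q, open_arms)
    arm2 = arm.copy()
    arm2[post] = arm_post
    recruited2 = (~post & recruited) | (post & (arm2 >= 0))
    event_time2 = times_for(arm2)

    final_events = event_calendar_times(
        arm2[recruited2], entry[recruited2], event_time2[recruited2],
        censor[recruited2], [0, selected],
    )
    if final_events.size < design.final_trigger:
        raise InsufficientEventsError(
            f"final trigger {design.final_trigger} not reachable in arms "
            f"{{0, {selected}}}: only {final_events.size} events can ever be "
            "observed under the recruitment caps"
        )
    t2 = float(final_events[design.final_trigger - 1])

    if design.followup_dropped:
        final_mask = recruited2
        final_arms = range(K + 1)
    else:
        final_mask = recruited2 & np.isin(arm2, [0, selected])
        final_arms = [0, selected]
    snap2 = snapshot_arrays(
        arm2[final_mask], entry[final_mask], event_time2[final_mask],
        censor[final_mask], t2, ids=np.flatnonzero(final_mask),
    )
    fit2 = fit_cox(snap2, arms=final_arms, baseline_arm=0)

    patients = [
        PatientRecord(int(i), int(arm2[i]), float(entry[i]),
                      float(event_time2[i]), float(censor[i]))
        for i in np.flatnonzero(recruited2)
    ]
    return TrialRun(
        design=design, patients=patients, interim_time=t1, selected=selected,
        interim_snapshot=snap1, interim_fit=fit1, final_time=t2,
        final_snapshot=snap2, final_fit=fit2,
    )


def analyze_trial(patients: Sequence[PatientRecord], design: DesignSpec) -> TrialRun:
    """Re-run the event-driven two-stage analysis on recorded data.

    Determines the interim time from the interim trigger, fits the Cox
    model, selects the best arm, locates the final analysis time from
    the final trigger in control + selected, and fits the final model —
    the same analysis path the simulator takes, applied to a stored
    patient table.
    """
    from .core import _trial_arrays, calendar_time_of_event

    _, arm, entry, ev, cens = _trial_arrays(patients)
    t1 = calendar_time_of_event(patients, design.interim_trigger)
    snap1 = snapshot_arrays(arm, entry, ev, cens, t1)
    fit1 = fit_cox(snap1, arms=range(design.K + 1), baseline_arm=0)
    selected = int(fit1.arms[int(np.argmin(fit1.beta_hat))])
    t2 = calendar_time_of_event(patients, design.final_trigger, [0, selected])
    if design.followup_dropped:
        final_arms = range(design.K + 1)
        mask = np.ones_like(arm, dtype=bool)
    else:
        final_arms = [0, selected]
        mask = np.isin(arm, [0, selected])
    snap2 = snapshot_arrays(arm[mask], entry[mask], ev[mask], cens[mask], t2)
    fit2 = fit_cox(snap2, arms=final_arms, baseline_arm=0)
    return TrialRun(
        design=design, patients=list(patients), interim_time=t1,
        selected=selected, interim_snapshot=snap1, interim_fit=fit1,
        final_time=t2, final_snapshot=snap2, final_fit=fit2,
    )


def design_to_dict(design: DesignSpec) -> dict:
    """JSON/YAML-serializable view of a design (censoring hooks are not
    serializable and must be re-attached in code)."""
    return {
        "K": design.K,
        "max_per_group": design.max_per_group,
        "allocation": list(design.allocation.probs),
        "accrual_rate": design.accrual_rate,
        "baseline_hazard": design.baseline_hazard,
        "hazard_ratios": list(design.hazard_ratios),
        "interim_trigger": design.interim_trigger,
        "final_trigger": design.final_trigger,
        "followup_dropped": design.followup_dropped,
        "seed": design.seed,
    }


def design_from_dict(doc: dict) -> DesignSpec:
    """Inverse of :func:`design_to_dict`; accepts ``scenario`` as an
    alternative to explicit hazard ratios."""
    doc = dict(doc)
    K = int(doc.pop("K"))
    alloc = doc.pop("allocation", None)
    if alloc is not None:
        alloc = AllocationSpec(K=K, probs=tuple(float(p) for p in alloc))
    scenario = doc.pop("scenario", None)
    hrs = doc.pop("hazard_ratios", None)
    if scenario is not None:
        if hrs is not None:
            raise ValueError("give either scenario or hazard_ratios, not both")
        hrs = tuple(scenario_hazards(scenario, K))
    elif hrs is not None:
        hrs = tuple(float(h) for h in hrs)
    known = {
        "max_per_group", "accrual_rate", "baseline_hazard",
        "interim_trigger", "final_trigger", "followup_dropped", "seed",
    }
    extra = set(doc) - known
    if extra:
        raise ValueError(f"unknown design fields: {sorted(extra)}")
    return DesignSpec(K=K, allocation=alloc, hazard_ratios=hrs, **doc)


def with_scenario(design: DesignSpec, scenario: str) -> DesignSpec:
    """Copy of the design with the hazard ratios of a named scenario."""
    return replace(design, hazard_ratios=tuple(scenario_hazards(scenario, design.K)))
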