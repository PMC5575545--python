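"""Shared fixtures and hypothesis settings."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from armselect import DesignSpec, Snapshot, simulate_trial

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEED = 20170613  # suite-wide base seed


@pytest.fixture(scope="session")
def base_seed() -> int:
    return SEED


def make_snapshot(arms, followups, statuses, t=math.inf) -> Snapshot:
    return Snapshot(
        analysis_time=t,
        arm=np.asarray(arms, dtype=np.int64),
        followup=np.asarray(followups, dtype=float),
        status=np.asarray(statuses, dtype=np.int8),
    )


@pytest.fixture
def toy_two_arm_snapshot() -> Snapshot:
    """Six patients, two arms, two censored: the smallest dataset on
    which the Cox fit is interesting."""
    return make_snapshot(
        arms=[0, 0, 0, 1, 1, 1],
        followups=[1.0, 3.0, 5.0, 2.0, 4.0, 6.0],
        statuses=[1, 1, 0, 1, 1, 0],
    )


def exponential_snapshot(
    rng: np.random.Generator,
    n_per_arm: dict[int, int],
    hazards: dict[int, float],
    censor_at: float = math.inf,
) -> Snapshot:
    """Fully-followed-up exponential data without staggered entry."""
    arms, fups, stats = [], [], []
    for arm, n in n_per_arm.items():
        t = rng.exponential(1.0 / hazards[arm], n)
        obs = t <= censor_at
        arms.extend([arm] * n)
        fups.extend(np.where(obs, t, censor_at).tolist())
        stats.extend(obs.astype(int).tolist())
    return make_snapshot(arms, fups, stats)


@pytest.fixture(scope="session")
def small_trial_run():
    """One complete two-stage K=3 trial shared across tests."""
    design = DesignSpec(K=3, hazard_ratios=(1.0, 0.8, 0.9))
    return simulate_trial(design, seed=SEED)
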