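"""Simulation study harness: bias and RMSE of all estimators.

Replicates event-driven two-stage trials over a grid of scenarios,
numbers of treatment arms and allocation ratios, applies every
requested estimator at the interim analysis, the final analysis and as
a two-stage combination, and aggregates the selected-arm estimation
error.  The headline metrics per cell are

    bias = mean(estimate_S - beta_S),
    rmse = sqrt(mean((estimate_S - beta_S)^2)),

the prediction form of the mean squared error (``beta_S`` is the true
log-HR of the *randomly selected* arm, so it varies across replicates);
the alternative definition, error relative to ``E[beta_S]``, is
available behind a flag.  Monte-Carlo standard errors, exclusion counts
(replicates where an event trigger was unreachable) and the
Stallard-Todd fallback rate are reported alongside.

Everything is deterministic given the study seed: each replicate draws
its own child seed from a fixed spawn tree, so cells can be recomputed
independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .asymptotics import AllocationSpec, pairwise_correlation
from .core import ArmselectError
from .estimators import METHODS, STAGES, build_context, estimate_all
from .selection import FAST, Quadrature
from .simulate import DesignSpec, scenario_hazards, simulate_trial

__all__ = ["StudyConfig", "run_study", "mse_curve_vs_correlation"]

logger = logging.getLogger("armselect.study")


@dataclass(frozen=True)
class StudyConfig:
    """Grid and size of a simulation study.

    ``allocation_ratios`` are control:treatment pairs ``(m, n)`` with
    equal treatment arms; ``design_overrides`` is forwarded to
    :class:`DesignSpec` (e.g. ``{"final_trigger": 300}``).
    """

    scenarios: tuple[str, ...] = ("constant", "linear", "peak")
    K_values: tuple[int, ...] = (4,)
    allocation_ratios: tuple[tuple[float, float], ...] = ((1, 1),)
    replicates: int = 2000
    methods: tuple[str, ...] = METHODS
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    weight: float | None = None  # None: information fraction d1/d2
    mse_of_mean: bool = False    # also report error about E[beta_S]
    selection_quadrature: Quadrature = FAST
    design_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.scenarios) - {"constant", "linear", "peak"}
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")


def _cell_design(config: StudyConfig, scenario: str, K: int,
                 ratio: tuple[float, float]) -> DesignSpec:
    return DesignSpec(
        K=K,
        allocation=AllocationSpec.from_ratio(K, *ratio),
        hazard_ratios=tuple(scenario_hazards(scenario, K)),
        **config.design_overrides,
    )


def _run_cell(config: StudyConfig, scenario: str, K: int,
              ratio: tuple[float, float], cell_index: int) -> list[dict]:
    design = _cell_design(config, scenario, K, ratio)
    loghr = design.log_hazard_ratios()
    seeds = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(cell_index,)
    ).spawn(config.replicates)

    errors: dict[tuple[str, str], list[float]] = {}
    estimates: dict[tuple[str, str], list[float]] = {}
    fallbacks: dict[tuple[str, str], int] = {}
    true_vals: list[float] = []
    n_excluded = 0
    for r, child in enumerate(seeds):
        try:
            run = simulate_trial(design, seed=child)
            ctx = build_context(
                run.interim_fit, run.final_fit, run.selected,
                weight=config.weight,
                selection_quadrature=config.selection_quadrature,
            )
            ests = estimate_all(ctx, config.methods, config.stages)
        except ArmselectError as exc:
            n_excluded += 1
            logger.debug("replicate %d excluded: %s", r, exc)
            continue
        beta_s = float(loghr[run.selected - 1])
        true_vals.append(beta_s)
        for key, est in ests.items():
            val = est.for_arm(run.selected)
            errors.setdefault(key, []).append(val - beta_s)
            estimates.setdefault(key, []).append(val)
            if est.fallback_used:
                fallbacks[key] = fallbacks.get(key, 0) + 1
        logger.debug("replicate %d/%d done (selected arm %d)",
                     r + 1, config.replicates, run.selected)

    mean_beta_s = float(np.mean(true_vals)) if true_vals else math.nan
    rows = []
    for (method, stage), errs in errors.items():
        e = np.asarray(errs)
        n = e.shape[0]
        row = {
            "scenario": scenario,
            "K": K,
            "ratio": f"{ratio[0]:g}:{ratio[1]:g}",
            "method": method,
            "stage": stage,
            "bias": float(e.mean()),
            "rmse": float(np.sqrt(np.mean(e**2))),
            "mc_se": float(e.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
            "n_eff": n,
            "n_excluded": n_excluded,
            "nonconvergence_rate": (
                fallbacks.get((method, stage), 0) / n if method == "ST" else math.nan
            ),
        }
        if config.mse_of_mean:
            a = np.asarray(estimates[(method, stage)]) - mean_beta_s
            row["rmse_of_mean"] = float(np.sqrt(np.mean(a**2)))
        rows.append(row)
    return rows


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Run the full study grid; one row per
    (scenario, K, ratio, method, stage)."""
    rows: list[dict] = []
    cell_index = 0
    for scenario in config.scenarios:
        for K in config.K_values:
            for ratio in config.allocation_ratios:
                logger.info("cell %s K=%d ratio=%s (%d replicates)",
                            scenario, K, ratio, config.replicates)
                rows.extend(_run_cell(config, scenario, K, ratio, cell_index))
                cell_index += 1
    df = pd.DataFrame(rows)
    order = ["scenario", "K", "ratio", "method", "stage"]
    return df.sort_values(order).reset_index(drop=True)


def mse_curve_vs_correlation(config: StudyConfig) -> pd.DataFrame:
    """Two-stage bias/RMSE as a function of the allocation-induced
    correlation.

    Runs the two-stage estimators over the configured allocation ratios
    and annotates each row with the analytic correlation between any
    two log-HR estimators under that allocation.  With the usual five
    ratios (3:1 ... 1:3) the correlations are 1/4, 1/3, 1/2, 2/3, 3/4.
    """
    from dataclasses import replace

    cfg = replace(config, stages=("two_stage",))
    df = run_study(cfg)
    corr = {}
    for ratio in cfg.allocation_ratios:
        K = cfg.K_values[0]
        alloc = AllocationSpec.from_ratio(K, *ratio)
        corr[f"{ratio[0]:g}:{ratio[1]:g}"] = pairwise_correlation(alloc, 1, 2)
    df["correlation"] = df["ratio"].map(corr)
    return df.sort_values(["scenario", "K", "correlation", "method"]).reset_index(
        drop=True
    )
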