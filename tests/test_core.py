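"""Snapshot logic, Cox partial likelihood, Kaplan-Meier, I/O."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from armselect import (
    DesignSpec,
    InsufficientEventsError,
    MonotoneLikelihoodError,
    NoEventsError,
    PatientRecord,
    calendar_time_of_event,
    fit_cox,
    kaplan_meier,
    pooled_loghr,
    read_patient_table,
    score_info_at,
    simulate_trial,
    snapshot,
    treatment_only_statistic,
    write_patient_table,
)
from conftest import SEED, exponential_snapshot, make_snapshot


# ---------------------------------------------------------------------------
# snapshot
# ---------------------------------------------------------------------------

class TestSnapshot:
    def test_event_after_analysis_time_is_censored(self):
        trial = [PatientRecord(0, 0, entry=2.0, event_time=5.0)]
        snap = snapshot(trial, 4.0)
        assert snap.n_recruited == 1
        assert snap.followup[0] == pytest.approx(2.0)
        assert snap.status[0] == 0

    def test_event_before_analysis_time_is_observed(self):
        trial = [PatientRecord(0, 0, entry=2.0, event_time=5.0)]
        snap = snapshot(trial, 10.0)
        assert snap.followup[0] == pytest.approx(5.0)
        assert snap.status[0] == 1

    def test_unrecruited_patient_absent(self):
        trial = [PatientRecord(0, 0, entry=6.0, event_time=1.0)]
        assert snapshot(trial, 4.0).n_recruited == 0

    def test_random_censoring_respected(self):
        trial = [PatientRecord(0, 1, entry=0.0, event_time=5.0, censor_time=3.0)]
        snap = snapshot(trial, 10.0)
        assert snap.followup[0] == pytest.approx(3.0)
        assert snap.status[0] == 0

    @given(
        t1=st.floats(0.0, 30.0),
        dt=st.floats(0.0, 30.0),
        data=st.lists(
            st.tuples(
                st.floats(0.0, 20.0),   # entry
                st.floats(0.01, 40.0),  # event time
            ),
            min_size=1,
            max_size=25,
        ),
    )
    def test_snapshot_nesting(self, t1, dt, data):
        """Every event visible at t is visible at any later t'."""
        trial = [
            PatientRecord(i, 0, entry=e, event_time=ev)
            for i, (e, ev) in enumerate(data)
        ]
        s1 = snapshot(trial, t1)
        s2 = snapshot(trial, t1 + dt)
        assert s1.status.sum() <= s2.status.sum()
        assert s1.n_recruited <= s2.n_recruited

    def test_event_counts_nondecreasing_on_simulated_trial(self):
        run = simulate_trial(DesignSpec(K=2), seed=SEED)
        counts = [
            snapshot(run.patients, t).status.sum()
            for t in np.linspace(0.0, run.final_time, 12)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# calendar_time_of_event
# ---------------------------------------------------------------------------

class TestCalendarTimeOfEvent:
    def _three(self):
        return [
            PatientRecord(i, 0, entry=0.0, event_time=float(i + 1))
            for i in range(3)
        ]

    def test_dth_event_time(self):
        assert calendar_time_of_event(self._three(), 2, [0]) == pytest.approx(2.0)

    def test_insufficient_events(self):
        with pytest.raises(InsufficientEventsError):
            calendar_time_of_event(self._three(), 4, [0])

    @pytest.mark.parametrize("d", [5, 40, 150])
    def test_snapshot_at_returned_time_recounts_exactly(self, d):
        """Re-count oracle on a seeded simulated mixed-arm trial."""
        run = simulate_trial(DesignSpec(K=3), seed=SEED + 1)
        t = calendar_time_of_event(run.patients, d)
        assert snapshot(run.patients, t).status.sum() == d

    def test_arm_restriction(self):
        trial = self._three() + [
            PatientRecord(9, 1, entry=0.0, event_time=0.5)
        ]
        # arm-1 event does not count toward an arms={0} trigger
        assert calendar_time_of_event(trial, 1, [0]) == pytest.approx(1.0)
        assert calendar_time_of_event(trial, 1, [0, 1]) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# fit_cox
# ---------------------------------------------------------------------------

def breslow_loglik_1d(snap, beta_grid):
    """Independent direct evaluation of the Breslow log partial
    likelihood for a two-group snapshot (covariate = arm indicator)."""
    z = (snap.arm == 1).astype(float)
    out = np.zeros_like(beta_grid)
    for t, d in zip(snap.followup[snap.status == 1], z[snap.status == 1]):
        at_risk = snap.followup >= t
        out += d * beta_grid - np.log(
            np.sum(
                np.exp(beta_grid[:, None] * z[None, at_risk]), axis=1
            )
        )
    return out


class TestFitCox:
    def test_no_events_error(self):
        snap = make_snapshot([0, 1], [1.0, 2.0], [0, 0])
        with pytest.raises(NoEventsError):
            fit_cox(snap)

    def test_matches_grid_search_oracle(self, toy_two_arm_snapshot):
        grid = np.arange(-5.0, 5.0, 1e-4)
        ll = breslow_loglik_1d(toy_two_arm_snapshot, grid)
        beta_grid = grid[np.argmax(ll)]
        fit = fit_cox(toy_two_arm_snapshot)
        assert fit.beta_hat[0] == pytest.approx(beta_grid, abs=1e-4)

    def test_matches_lifelines(self, toy_two_arm_snapshot):
        """Independent cross-check against an established fitter."""
        import pandas as pd
        from lifelines import CoxPHFitter

        snap = toy_two_arm_snapshot
        df = pd.DataFrame({
            "T": snap.followup, "E": snap.status,
            "z": (snap.arm == 1).astype(float),
        })
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        fit = fit_cox(snap)
        assert fit.beta_hat[0] == pytest.approx(
            float(cph.params_["z"]), abs=1e-6
        )
        assert fit.cov_hat[0, 0] == pytest.approx(
            float(cph.variance_matrix_.iloc[0, 0]), rel=1e-4
        )

    def test_score_stationary_and_info_matches_finite_difference(
        self, toy_two_arm_snapshot
    ):
        fit = fit_cox(toy_two_arm_snapshot)
        assert np.max(np.abs(fit.score)) < 1e-8
        h = 1e-5
        grid = np.array([fit.beta_hat[0] - h, fit.beta_hat[0], fit.beta_hat[0] + h])
        ll = breslow_loglik_1d(toy_two_arm_snapshot, grid)
        num_info = -(ll[0] - 2 * ll[1] + ll[2]) / h**2
        assert fit.information[0, 0] == pytest.approx(num_info, rel=1e-4)

    def test_monotone_likelihood_detected(self):
        # all events in the control arm: beta diverges to -inf
        snap = make_snapshot(
            [0, 0, 0, 1, 1, 1], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [1, 1, 1, 0, 0, 0],
        )
        with pytest.raises(MonotoneLikelihoodError):
            fit_cox(snap)

    def test_events_per_arm_sums_to_total(self, small_trial_run):
        fit = small_trial_run.final_fit
        assert fit.total_events == int(fit.events_per_arm.sum())
        assert fit.total_events == int(small_trial_run.final_snapshot.status.sum())

    def test_cov_positive_definite(self, small_trial_run):
        for fit in (small_trial_run.interim_fit, small_trial_run.final_fit):
            np.linalg.cholesky(fit.cov_hat)  # raises if not PD
            assert np.allclose(fit.cov_hat, fit.cov_hat.T)

    def test_multiarm_recovers_true_loghr(self):
        """Large-sample consistency on fully observed exponential data."""
        rng = np.random.default_rng(SEED)
        snap = exponential_snapshot(
            rng, {0: 4000, 1: 4000, 2: 4000},
            {0: 0.1, 1: 0.1 * 0.6, 2: 0.1 * 1.2},
        )
        fit = fit_cox(snap)
        assert fit.beta_hat[0] == pytest.approx(math.log(0.6), abs=0.06)
        assert fit.beta_hat[1] == pytest.approx(math.log(1.2), abs=0.06)


class TestScoreInfoAt:
    def test_score_vanishes_at_mle(self, small_trial_run):
        fit = small_trial_run.interim_fit
        U, _ = score_info_at(small_trial_run.interim_snapshot, fit.beta_hat)
        assert np.max(np.abs(U)) < 1e-7

    def test_score_at_zero_equals_logrank_numerator(self, toy_two_arm_snapshot):
        """For K=1 the score at beta=0 is the observed-minus-expected
        log-rank numerator."""
        snap = toy_two_arm_snapshot
        U, _ = score_info_at(snap, [0.0])
        o_minus_e = 0.0
        for t, a in zip(snap.followup[snap.status == 1],
                        snap.arm[snap.status == 1]):
            at_risk = snap.followup >= t
            expected = np.mean(snap.arm[at_risk] == 1)
            o_minus_e += (a == 1) - expected
        assert U[0] == pytest.approx(o_minus_e, abs=1e-12)

    def test_information_symmetric_psd(self, small_trial_run):
        for beta in ([0.0, 0.0, 0.0], [0.5, -0.3, 0.2]):
            _, info = score_info_at(small_trial_run.interim_snapshot, beta)
            assert np.allclose(info, info.T)
            assert np.min(np.linalg.eigvalsh(info)) >= -1e-10

    def test_information_increments_psd(self, small_trial_run):
        """Nested snapshots accumulate information (independent
        increments of the score process)."""
        run = small_trial_run
        for beta in ([0.0, 0.0, 0.0], [0.1, -0.1, 0.05]):
            _, i1 = score_info_at(run.interim_snapshot, beta)
            _, i2 = score_info_at(run.final_snapshot, beta)
            assert np.min(np.linalg.eigvalsh(i2 - i1)) >= -1e-8


# ---------------------------------------------------------------------------
# treatment-only statistic & pooled log-HR
# ---------------------------------------------------------------------------

class TestTreatmentOnlyStatistic:
    def test_symmetric_arms_give_near_zero(self):
        fups = [1.0, 2.0, 3.0, 4.0]
        # identical event-time multisets, ties broken in alternating
        # directions so neither arm systematically precedes the other
        shifted = [1.0 - 1e-4, 2.0 + 1e-4, 3.0 - 1e-4, 4.0 + 1e-4]
        snap = make_snapshot([1] * 4 + [2] * 4, fups + shifted, [1] * 8)
        # tiny residual remains because risk sets shrink between the
        # paired events; "near zero" on the chi-square(1) scale
        assert treatment_only_statistic(snap) < 0.1

    def test_chi_square_mean_under_null(self):
        """K=4 equal treatment arms: the statistic is approximately
        chi-square with 3 df (mean 3)."""
        rng = np.random.default_rng(SEED)
        vals = [
            treatment_only_statistic(
                exponential_snapshot(
                    rng, {k: 60 for k in range(1, 5)},
                    {k: 0.1 for k in range(1, 5)},
                )
            )
            for _ in range(400)
        ]
        se = math.sqrt(6.0 / len(vals))
        assert np.mean(vals) == pytest.approx(3.0, abs=4 * se)

    def test_close_to_wald_on_large_sample(self):
        """Score and Wald forms agree asymptotically."""
        rng = np.random.default_rng(SEED + 2)
        snap = exponential_snapshot(
            rng, {k: 2000 for k in range(1, 4)},
            {1: 0.10, 2: 0.11, 3: 0.095},
        )
        z_score = treatment_only_statistic(snap)
        fit = fit_cox(snap.restrict([1, 2, 3]), arms=[1, 2, 3], baseline_arm=1)
        wald = float(fit.beta_hat @ np.linalg.solve(fit.cov_hat, fit.beta_hat))
        assert z_score == pytest.approx(wald, rel=0.15)


class TestPooledLogHR:
    def test_single_arm_pooling_is_identity(self, toy_two_arm_snapshot):
        fit = fit_cox(toy_two_arm_snapshot)
        assert pooled_loghr(toy_two_arm_snapshot) == pytest.approx(
            float(fit.beta_hat[0]), abs=1e-10
        )

    def test_identical_arms_pool_to_zero(self):
        rng = np.random.default_rng(SEED + 3)
        snap = exponential_snapshot(
            rng, {0: 3000, 1: 1500, 2: 1500}, {0: 0.1, 1: 0.1, 2: 0.1}
        )
        assert abs(pooled_loghr(snap)) < 0.06

    def test_pooled_between_armwise_estimates(self):
        rng = np.random.default_rng(SEED + 4)
        snap = exponential_snapshot(
            rng, {0: 3000, 1: 3000, 2: 3000}, {0: 0.1, 1: 0.06, 2: 0.1}
        )
        fit = fit_cox(snap)
        pooled = pooled_loghr(snap)
        lo, hi = sorted(fit.beta_hat)
        assert lo < pooled < hi


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_textbook_product_limit(self):
        snap = make_snapshot([0, 0, 0], [1.0, 2.0, 3.0], [1, 1, 0])
        km = kaplan_meier(snap, 0)
        assert km(0.5) == pytest.approx(1.0)
        assert km(1.0) == pytest.approx(2 / 3)
        assert km(2.5) == pytest.approx(1 / 3)

    def test_no_events_survival_one(self):
        snap = make_snapshot([0, 0], [1.0, 2.0], [0, 0])
        km = kaplan_meier(snap, 0)
        assert km(1.5) == pytest.approx(1.0)

    def test_exponential_median(self):
        rng = np.random.default_rng(SEED + 5)
        lam = math.log(2) / 12
        snap = exponential_snapshot(rng, {0: 20000}, {0: lam})
        km = kaplan_meier(snap, 0)
        assert km(12.0) == pytest.approx(0.5, abs=0.02)

    def test_cox_power_relationship(self):
        """On large proportional-hazards data, S_1 is approximately
        S_0 raised to the hazard ratio."""
        rng = np.random.default_rng(SEED + 6)
        hr = 0.6
        snap = exponential_snapshot(
            rng, {0: 6000, 1: 6000}, {0: 0.1, 1: 0.1 * hr}
        )
        km0 = kaplan_meier(snap, 0)
        km1 = kaplan_meier(snap, 1)
        for t in (5.0, 10.0, 15.0):
            assert km1(t) == pytest.approx(km0(t) ** hr, abs=0.03)


# ---------------------------------------------------------------------------
# patient tables
# ---------------------------------------------------------------------------

class TestPatientTable:
    def test_round_trip(self, tmp_path, small_trial_run):
        path = tmp_path / "trial.csv"
        write_patient_table(path, small_trial_run.patients)
        back = read_patient_table(path)
        assert len(back) == len(small_trial_run.patients)
        for a, b in zip(small_trial_run.patients, back):
            assert a.id == b.id and a.arm == b.arm
            assert a.entry == pytest.approx(b.entry)
            assert a.event_time == pytest.approx(b.event_time)

    def test_reader_validates_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,arm,entry\n0,0,0.0\n")
        with pytest.raises(ValueError, match="lacks columns"):
            read_patient_table(path)

    def test_reader_validates_status(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,arm,entry,time,status\n0,0,0.0,1.0,2\n")
        with pytest.raises(ValueError, match="status"):
            read_patient_table(path)

    def test_censored_round_trip(self, tmp_path):
        path = tmp_path / "c.csv"
        trial = [
            PatientRecord(0, 1, entry=0.5, event_time=2.0),
            PatientRecord(1, 0, entry=1.0, event_time=9.0, censor_time=3.0),
        ]
        write_patient_table(path, trial)
        back = read_patient_table(path)
        assert back[1].censor_time == pytest.approx(3.0)
        assert math.isinf(back[1].event_time)
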