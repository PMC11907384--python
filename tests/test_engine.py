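import dataclasses

import numpy as np
import pytest

from platsim import (
    AllocationRule,
    ArmSpec,
    ArmStatus,
    DomainSpec,
    Scenario,
    StoppingRules,
    TrialResult,
    calibrate_superiority_threshold,
    run_batch,
    run_trial,
    summarise_metrics,
)
from platsim.engine import CalibrationError


def no_rules(spec):
    return dataclasses.replace(spec, stopping=StoppingRules(1.0, 0.0))


def with_thresholds(spec, sup, inf=None):
    return dataclasses.replace(
        spec, stopping=StoppingRules(sup, 1 - sup if inf is None else inf)
    )


def result_equal(a: TrialResult, b: TrialResult) -> bool:
    return (
        a.stop_reason == b.stop_reason
        and a.selected_arm == b.selected_arm
        and a.n_randomised == b.n_randomised
        and np.array_equal(a.n_per_arm, b.n_per_arm)
        and np.array_equal(a.events_per_arm, b.events_per_arm)
        and a.looks_done == b.looks_done
        and np.array_equal(a.final_alpha, b.final_alpha)
        and np.array_equal(a.final_posterior_median, b.final_posterior_median)
        and a.statuses == b.statuses
        and a.config_hash == b.config_hash
    )


class TestRunTrial:
    def test_disabled_rules_always_inconclusive_at_exactly_max_n(
        self, three_arm_spec, null_scenario
    ):
        r = run_trial(no_rules(three_arm_spec), null_scenario, seed=1, n_draws=500)
        assert r.stop_reason == "inconclusive_max_n"
        assert r.selected_arm is None
        assert r.n_randomised == three_arm_spec.max_n

    def test_same_seed_replays_bit_exact(self, three_arm_spec, null_scenario):
        r1 = run_trial(three_arm_spec, null_scenario, seed=42, n_draws=1000)
        r2 = run_trial(three_arm_spec, null_scenario, seed=42, n_draws=1000)
        assert result_equal(r1, r2)

    def test_overwhelming_separation_stops_for_superiority(self):
        spec = DomainSpec(
            arms=[ArmSpec("A"), ArmSpec("B")],
            comparison="all_vs_all", direction="lower_better",
            stopping=StoppingRules(0.99, 0.01),
            allocation=AllocationRule(mode="fixed_equal"),
            first_look_n=100, look_interval_n=100, max_n=2000,
            followup_days=5, data_verification_days=5,
        )
        scenario = Scenario((0.9, 0.1), accrual_rate=20.0, label="separated")
        for seed in range(10):
            r = run_trial(spec, scenario, seed=seed, n_draws=1000)
            assert r.stop_reason == "superiority"
            assert r.selected_arm == 1  # the low-mortality arm

    def test_patient_conservation(self, three_arm_spec, null_scenario):
        r = run_trial(three_arm_spec, null_scenario, seed=3, n_draws=500)
        assert r.n_per_arm.sum() == r.n_randomised
        assert np.all(r.events_per_arm <= r.n_per_arm)

    def test_stopped_trial_randomises_no_further_patients(self, null_scenario):
        spec = DomainSpec(
            arms=[ArmSpec("A"), ArmSpec("B"), ArmSpec("C")],
            comparison="all_vs_all", direction="lower_better",
            stopping=StoppingRules(
                0.6, 0.2, equivalence_margin=0.1, equivalence_prob_threshold=0.6
            ),
            allocation=AllocationRule(mode="fixed_equal"),
            first_look_n=100, look_interval_n=100, max_n=600,
            followup_days=5, data_verification_days=5,
        )
        r = run_trial(spec, null_scenario, seed=5, n_draws=500)
        assert r.stop_reason in ("superiority", "equivalence")
        assert r.n_randomised < spec.max_n
        # randomised count was frozen at the stopping look
        assert r.audit[-1]["stopped"]
        assert r.audit[-1]["n_randomised"] == r.n_randomised

    def test_common_control_keeps_exactly_one_control(self, common_control_spec):
        scenario = Scenario((0.35, 0.22, 0.30), accrual_rate=20.0, label="ctrl-worst")
        for seed in range(5):
            r = run_trial(common_control_spec, scenario, seed=seed, n_draws=1000)
            for look in r.audit:
                for p in look["passes"]:
                    assert p["control"] is not None
            n_controls = sum(s == ArmStatus.CONTROL for s in r.statuses)
            assert n_controls <= 1

    def test_period_increments_with_adaptations(self, three_arm_spec, null_scenario):
        # RAR updates allocation after every look, so each look opens a period
        r = run_trial(three_arm_spec, null_scenario, seed=8, n_draws=500)
        assert r.n_periods >= r.looks_done - 1


class TestRunBatch:
    def test_single_trial_batch_equals_trial_indicators(self, three_arm_spec, null_scenario):
        results, metrics = run_batch(three_arm_spec, null_scenario, 1, seed=4, n_draws=500)
        r = results[0]
        assert metrics.n_sims == 1
        assert metrics.expected_n == r.n_randomised
        assert metrics.p_superiority_stop == float(r.stop_reason == "superiority")
        assert metrics.sd_n == 0.0

    def test_rules_disabled_batch_runs_to_max_n(self, three_arm_spec, null_scenario):
        _, metrics = run_batch(no_rules(three_arm_spec), null_scenario, 5, seed=5, n_draws=300)
        assert metrics.expected_n == three_arm_spec.max_n
        assert metrics.p_conclusive == 0.0

    def test_batch_replays_bit_exact(self, three_arm_spec, null_scenario):
        res1, m1 = run_batch(three_arm_spec, null_scenario, 8, seed=6, n_draws=500)
        res2, m2 = run_batch(three_arm_spec, null_scenario, 8, seed=6, n_draws=500)
        assert all(result_equal(a, b) for a, b in zip(res1, res2))
        assert m1.to_json_dict() == m2.to_json_dict()

    def test_null_scenario_selects_each_arm_equally_often(self, null_scenario):
        spec = DomainSpec(
            arms=[ArmSpec("A"), ArmSpec("B"), ArmSpec("C")],
            comparison="all_vs_all", direction="lower_better",
            stopping=StoppingRules(0.7, 0.3),
            allocation=AllocationRule(mode="fixed_equal"),
            first_look_n=100, look_interval_n=100, max_n=600,
            followup_days=5, data_verification_days=5,
        )
        _, metrics = run_batch(spec, null_scenario, 150, seed=7, n_draws=500)
        sel = metrics.p_select_arm
        assert sel.sum() > 0.5  # loose thresholds select often
        p_bar = sel.mean()
        se = np.sqrt(p_bar * (1 - p_bar) / 150)
        assert np.all(np.abs(sel - p_bar) < 3 * se + 0.02)

    def test_better_arm_selected_no_less_often_under_dominance(self, three_arm_spec):
        spec = with_thresholds(three_arm_spec, 0.9)
        base = Scenario((0.25, 0.25, 0.25), 20.0, "null")
        better = Scenario((0.25, 0.25, 0.15), 20.0, "one-better")
        _, m_base = run_batch(spec, base, 60, seed=8, n_draws=500)
        _, m_better = run_batch(spec, better, 60, seed=8, n_draws=500)
        assert m_better.p_select_arm[2] >= m_base.p_select_arm[2]


class TestSummariseMetrics:
    @staticmethod
    def make_result(stop_reason, selected, n_per_arm, median, n_arms=2):
        n_per_arm = np.asarray(n_per_arm)
        return TrialResult(
            stop_reason=stop_reason,
            selected_arm=selected,
            n_randomised=int(n_per_arm.sum()),
            n_per_arm=n_per_arm,
            events_per_arm=np.zeros(n_arms, dtype=int),
            looks_done=3,
            final_alpha=np.ones(n_arms),
            final_beta=np.ones(n_arms),
            final_posterior_median=np.asarray(median),
            statuses=[ArmStatus.ACTIVE] * n_arms,
            n_periods=1,
        )

    def test_counts_superiority_fraction(self):
        results = [
            self.make_result("superiority", 0, [50, 50], [0.2, 0.2]) for _ in range(7)
        ] + [
            self.make_result("inconclusive_max_n", None, [50, 50], [0.2, 0.2])
            for _ in range(3)
        ]
        scenario = Scenario((0.2, 0.3), 10.0, "s")
        m = summarise_metrics(results, scenario, "lower_better")
        assert m.p_superiority_stop == pytest.approx(0.7)
        assert m.p_conclusive == pytest.approx(0.7)
        assert m.p_select_arm[0] == pytest.approx(0.7)

    def test_all_patients_on_best_arm(self):
        results = [self.make_result("superiority", 0, [100, 0], [0.2, 0.2])]
        m = summarise_metrics(results, Scenario((0.2, 0.3), 10.0, "s"), "lower_better")
        assert m.prop_allocated_best == 1.0

    def test_rmse_of_known_errors(self):
        results = [
            self.make_result("superiority", 0, [50, 50], [0.21, 0.3]),
            self.make_result("superiority", 0, [50, 50], [0.19, 0.3]),
        ]
        m = summarise_metrics(results, Scenario((0.2, 0.3), 10.0, "s"), "lower_better")
        assert m.rmse_event_prob == pytest.approx(0.01)

    def test_ties_count_all_best_arms(self):
        results = [self.make_result("superiority", 0, [60, 40], [0.2, 0.2])]
        m = summarise_metrics(results, Scenario((0.2, 0.2), 10.0, "null"), "lower_better")
        assert m.prop_allocated_best == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarise_metrics([], Scenario((0.2, 0.2), 10.0, "s"), "lower_better")


class TestCalibration:
    def test_type1_error_monotone_in_threshold(self, three_arm_spec, null_scenario):
        # same common-seed batch at a loose and a strict threshold
        loose = with_thresholds(three_arm_spec, 0.80)
        strict = with_thresholds(three_arm_spec, 0.999)
        _, m_loose = run_batch(loose, null_scenario, 60, seed=9, n_draws=500)
        _, m_strict = run_batch(strict, null_scenario, 60, seed=9, n_draws=500)
        assert m_loose.p_superiority_stop >= m_strict.p_superiority_stop

    def test_calibration_meets_target_on_common_batch(self, three_arm_spec, null_scenario):
        cal = calibrate_superiority_threshold(
            three_arm_spec, null_scenario, target=0.05, n_sims=60, seed=10,
            n_draws=500, tol=0.01,
        )
        assert cal.achieved_type1 <= 0.05
        assert 0.95 <= cal.superiority_threshold <= 0.9995
        assert len(cal.trace) >= 2
        assert cal.inferiority_threshold == pytest.approx(1 - cal.superiority_threshold)

    def test_calibration_replays_bit_exact(self, three_arm_spec, null_scenario):
        kw = dict(target=0.05, n_sims=30, seed=11, n_draws=400, tol=0.02)
        c1 = calibrate_superiority_threshold(three_arm_spec, null_scenario, **kw)
        c2 = calibrate_superiority_threshold(three_arm_spec, null_scenario, **kw)
        assert c1 == c2

    def test_rejects_non_null_scenario(self, three_arm_spec):
        with pytest.raises(ValueError):
            calibrate_superiority_threshold(
                three_arm_spec, Scenario((0.3, 0.2, 0.2), 10.0, "alt"), n_sims=5
            )

    def test_unattainable_target_reported(self, three_arm_spec, null_scenario):
        with pytest.raises(CalibrationError):
            calibrate_superiority_threshold(
                three_arm_spec, null_scenario, target=1e-6, n_sims=40, seed=12,
                n_draws=300, bounds=(0.6, 0.7),
            )


class TestExports:
    def test_patient_log_respects_lag_and_conservation(self, three_arm_spec, null_scenario):
        r = run_trial(three_arm_spec, null_scenario, seed=13, n_draws=300, keep_patients=True)
        log = r.patients
        assert len(log) == r.n_randomised
        lag = three_arm_spec.outcome_lag_days
        assert np.allclose(log["lag_complete_day"], log["arrival_day"] + lag)
        assert log["arrival_day"].is_monotonic_increasing
        counts = log.groupby("arm").size()
        for arm, n in counts.items():
            assert r.n_per_arm[arm] == n

    def test_jsonl_roundtrip(self, tmp_path, three_arm_spec, null_scenario):
        import gzip
        import json

        from platsim.engine import write_results_jsonl

        results, _ = run_batch(three_arm_spec, null_scenario, 3, seed=14, n_draws=300)
        path = tmp_path / "trials.jsonl.gz"
        write_results_jsonl(results, path)
        with gzip.open(path, "rt") as fh:
            lines = [json.loads(line) for line in fh]
        assert len(lines) == 3
        assert lines[0]["n_randomised"] == results[0].n_randomised
        assert lines[2]["seed"] == [14, 2]
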