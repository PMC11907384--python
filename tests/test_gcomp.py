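import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from platsim import (
    ModelConfig,
    OutcomeCoefficients,
    fit_outcome_model,
    generate_patient_table,
    marginal_contrasts,
    true_marginal_risks,
)
from platsim.gcomp import RD05_ARM_LOG_OR


def flat_coeffs(intercept, arm=(0.0, 0.0)):
    """Coefficients with every covariate effect zeroed."""
    zeros = dict(age=0, age2=0, severity=0, severity2=0, frailty=0, frailty2=0,
                 sex=0, cancer=0, surgery=0, imv=0, vasopressor=0, rrt=0,
                 site=(0.0,) * 8)
    return OutcomeCoefficients(intercept=intercept, arm=arm, **zeros)


class TestGenerator:
    def test_intercept_only_event_rate(self):
        n = 10_000
        table = generate_patient_table(n, flat_coeffs(float(logit(0.2))), seed=1)
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(table["event"].mean() - 0.2) < 3 * se

    def test_zero_arm_effect_gives_zero_true_marginal_rd(self):
        table = generate_patient_table(2_000, seed=2)
        risks = true_marginal_risks(table, OutcomeCoefficients())
        assert risks[1] - risks[0] == pytest.approx(0.0, abs=1e-12)

    def test_plugin_truth_matches_realised_event_rates(self):
        # oracle: with randomised arms, the per-arm realised event rate is a
        # Monte-Carlo average of the same potential-outcome probabilities
        n = 200_000
        coeffs = OutcomeCoefficients(arm=(0.0, -0.3))
        table = generate_patient_table(n, coeffs, seed=3)
        truth = true_marginal_risks(table, coeffs)
        for a in (0, 1):
            sub = table[table["arm"] == a]
            se = np.sqrt(truth[a] * (1 - truth[a]) / len(sub))
            assert abs(sub["event"].mean() - truth[a]) < 3 * se

    def test_covariate_ranges(self):
        t = generate_patient_table(5_000, seed=4)
        assert t["severity"].between(0, 42).all()
        assert t["frailty"].between(1, 9).all()
        assert t["age"].between(18, 95).all()
        assert not t.isna().any().any()

    def test_deterministic_given_seed(self):
        t1 = generate_patient_table(500, seed=5)
        t2 = generate_patient_table(500, seed=5)
        pd.testing.assert_frame_equal(t1, t2)


class TestFit:
    def test_intercept_only_recovers_event_probability(self):
        # two arms, no covariate variation, 30/100 events in each arm:
        # the model collapses to a single-proportion estimate per arm
        n = 200
        table = pd.DataFrame({
            "arm": np.repeat([0, 1], 100),
            "event": np.tile(np.r_[np.ones(30), np.zeros(70)], 2).astype(int),
            "site": 0, "age": 60.0, "sex": 1, "cancer_flag": 0, "surgery_flag": 0,
            "imv_flag": 0, "vasopressor_flag": 0, "rrt_flag": 0,
            "severity": 20, "frailty": 4, "period": 0,
        })
        fit = fit_outcome_model(table, ModelConfig(n_draws=4000), seed=6)
        eff = marginal_contrasts(fit, table)
        for a in (0, 1):
            med = eff.marginal_risk[a][0]
            assert abs(med - 0.3) < 0.05

    def test_duplicate_covariate_columns_rejected(self):
        table = generate_patient_table(300, seed=7)
        table["vasopressor_flag"] = table["imv_flag"]  # identical non-constant columns
        with pytest.raises(ValueError, match="duplicate"):
            fit_outcome_model(table)

    def test_single_arm_table_rejected(self):
        table = generate_patient_table(300, seed=8)
        table["arm"] = 0
        with pytest.raises(ValueError, match="two arms"):
            fit_outcome_model(table)

    def test_recovers_true_marginal_rd_in_credible_interval(self):
        coeffs = OutcomeCoefficients(arm=(0.0, RD05_ARM_LOG_OR))
        table = generate_patient_table(6_000, coeffs, seed=9)
        truth = true_marginal_risks(table, coeffs)
        fit = fit_outcome_model(table, ModelConfig(n_draws=2000), seed=10)
        eff = marginal_contrasts(fit, table)
        med, lo, hi = eff.rd[(1, 0)]
        true_rd = truth[1] - truth[0]
        assert lo <= true_rd <= hi
        assert abs(med - true_rd) < 0.03

    def test_sceptical_prior_shrinks_arm_contrast(self):
        coeffs = OutcomeCoefficients(arm=(0.0, RD05_ARM_LOG_OR))
        table = generate_patient_table(2_000, coeffs, seed=11)
        weak = marginal_contrasts(
            fit_outcome_model(table, ModelConfig(n_draws=1000), seed=12), table
        )
        sceptical = marginal_contrasts(
            fit_outcome_model(
                table, ModelConfig(n_draws=1000, prior_scale_arm=1e-3), seed=12
            ),
            table,
        )
        assert abs(sceptical.rd[(1, 0)][0]) < 0.01
        assert abs(sceptical.rd[(1, 0)][0]) < abs(weak.rd[(1, 0)][0])

    def test_constant_covariate_does_not_change_the_analysis(self):
        table = generate_patient_table(1_000, seed=13)
        t0 = table.copy()
        t0["rrt_flag"] = 0
        t1 = table.copy()
        t1["rrt_flag"] = 1
        f0 = fit_outcome_model(t0, ModelConfig(n_draws=500), seed=14)
        f1 = fit_outcome_model(t1, ModelConfig(n_draws=500), seed=14)
        assert f0.coef_names == f1.coef_names
        np.testing.assert_allclose(f0.draws, f1.draws)

    def test_emcee_agrees_with_laplace_and_passes_diagnostics(self):
        coeffs = OutcomeCoefficients(arm=(0.0, RD05_ARM_LOG_OR))
        table = generate_patient_table(1_500, coeffs, seed=15)
        lap = fit_outcome_model(table, ModelConfig(n_draws=2000), seed=16)
        mc = fit_outcome_model(table, ModelConfig(method="emcee", n_draws=2000), seed=17)
        assert mc.converged, mc.diagnostics
        e_lap = marginal_contrasts(lap, table).rd[(1, 0)][0]
        e_mc = marginal_contrasts(mc, table).rd[(1, 0)][0]
        assert abs(e_lap - e_mc) < 0.015

    def test_non_convergent_mcmc_is_flagged_not_silent(self):
        table = generate_patient_table(400, seed=18)
        with pytest.warns(UserWarning, match="diagnostics"):
            fit = fit_outcome_model(
                table,
                ModelConfig(method="emcee", emcee_steps=60, emcee_burn=10, n_draws=200),
                seed=19,
            )
        assert not fit.converged


class TestMarginalContrasts:
    def test_forced_identical_arm_coefficients_give_exact_null(self):
        table = generate_patient_table(800, seed=20)
        fit = fit_outcome_model(table, ModelConfig(n_draws=500), seed=21)
        col = fit.arm_col[1]
        fit.draws[:, col] = 0.0  # force both arms onto the same coefficients
        eff = marginal_contrasts(fit, table)
        np.testing.assert_array_equal(eff.risk_draws[0], eff.risk_draws[1])
        assert eff.rd[(1, 0)] == (0.0, 0.0, 0.0)
        assert eff.rr[(1, 0)] == (1.0, 1.0, 1.0)

    def test_rd_antisymmetric_and_rr_inverts_under_pair_reversal(self):
        table = generate_patient_table(800, OutcomeCoefficients(arm=(0.0, -0.4)), seed=22)
        # odd draw count: the median is an exact order statistic, so the
        # monotone map x -> 1/x carries it over exactly
        fit = fit_outcome_model(table, ModelConfig(n_draws=801), seed=23)
        eff = marginal_contrasts(fit, table, pairs=[(1, 0), (0, 1)])
        med_f, lo_f, hi_f = eff.rd[(1, 0)]
        med_r, lo_r, hi_r = eff.rd[(0, 1)]
        assert med_f == pytest.approx(-med_r, abs=1e-12)
        assert lo_f == pytest.approx(-hi_r, abs=1e-12)
        assert eff.rr[(1, 0)][0] == pytest.approx(1 / eff.rr[(0, 1)][0], rel=1e-9)

    def test_marginal_risks_are_probabilities(self):
        table = generate_patient_table(500, seed=24)
        fit = fit_outcome_model(table, ModelConfig(n_draws=300), seed=25)
        eff = marginal_contrasts(fit, table)
        for a, draws in eff.risk_draws.items():
            assert np.all((draws > 0) & (draws < 1))

    def test_collapses_to_unadjusted_contrast_without_covariates(self):
        # intercept+arm model: G-computation equals the plain difference of
        # the two arms' modelled event probabilities
        rng = np.random.default_rng(26)
        n = 2_000
        arm = rng.integers(0, 2, n)
        event = rng.random(n) < np.where(arm == 1, 0.22, 0.30)
        table = pd.DataFrame({
            "arm": arm, "event": event.astype(int),
            "site": 0, "age": 60.0, "sex": 1, "cancer_flag": 0, "surgery_flag": 0,
            "imv_flag": 0, "vasopressor_flag": 0, "rrt_flag": 0,
            "severity": 20, "frailty": 4, "period": 0,
        })
        fit = fit_outcome_model(table, ModelConfig(n_draws=4000), seed=27)
        eff = marginal_contrasts(fit, table)
        unadjusted = (
            table.loc[table.arm == 1, "event"].mean()
            - table.loc[table.arm == 0, "event"].mean()
        )
        med, lo, hi = eff.rd[(1, 0)]
        assert abs(med - unadjusted) < 0.01
        assert lo < unadjusted < hi
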