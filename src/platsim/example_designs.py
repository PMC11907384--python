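"""A worked reference design: three arms, all-vs-all, mortality-type
guiding outcome.

The domain compares three interventions on a binary 30-day guiding
outcome (lower event probability is better) with a 15-day data
collection/verification window, so the outcome-data lag is 45 days.
Adaptive analyses run at 500 lag-complete patients and every 300
thereafter up to a maximum sample size of 8,000; allocation is
response-adaptive with softening exponent 0.5 and a 10% floor per arm.
Accrual is 10 patients/day.  Superiority/inferiority thresholds are
placeholders until calibrated by simulation to a <=5% probability of a
superiority stop under the null scenario.
"""

from __future__ import annotations

import dataclasses

from .design import (
    AllocationRule,
    ArmSpec,
    DomainSpec,
    Scenario,
    StoppingRules,
)

__all__ = [
    "example_three_arm_design",
    "example_null_scenario",
    "example_one_better_scenario",
    "with_equivalence_rule",
]


def example_three_arm_design(
    superiority_threshold: float = 0.99,
    inferiority_threshold: float | None = None,
) -> DomainSpec:
    """The reference 3-arm all-vs-all RAR domain (see module docstring)."""
    if inferiority_threshold is None:
        inferiority_threshold = 1.0 - superiority_threshold
    return DomainSpec(
        arms=[ArmSpec("A"), ArmSpec("B"), ArmSpec("C")],
        comparison="all_vs_all",
        direction="lower_better",
        stopping=StoppingRules(superiority_threshold, inferiority_threshold),
        allocation=AllocationRule(
            mode="rar", softening_gamma=0.5, min_allocation=0.10, max_allocation=1.0
        ),
        first_look_n=500,
        look_interval_n=300,
        max_n=8_000,
        followup_days=30.0,
        data_verification_days=15.0,
        prior_alpha=1.0,
        prior_beta=1.0,
        name="example-3arm-rar",
    )


def with_equivalence_rule(
    spec: DomainSpec, margin: float = 0.05, prob_threshold: float = 0.90
) -> DomainSpec:
    """Add a practical-equivalence stopping rule to a design."""
    return dataclasses.replace(
        spec,
        stopping=dataclasses.replace(
            spec.stopping,
            equivalence_margin=margin,
            equivalence_prob_threshold=prob_threshold,
        ),
    )


def example_null_scenario(event_prob: float = 0.25, accrual_rate: float = 10.0) -> Scenario:
    """No between-arm differences: identical event probability everywhere."""
    return Scenario((event_prob,) * 3, accrual_rate, label="null")


def example_one_better_scenario(accrual_rate: float = 10.0) -> Scenario:
    """One arm with a 7-point lower event probability than the other two."""
    return Scenario((0.25, 0.25, 0.18), accrual_rate, label="one-better")
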