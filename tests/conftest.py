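import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from platsim import (
    AllocationRule,
    ArmSpec,
    DomainSpec,
    Scenario,
    StoppingRules,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def three_arm_spec():
    """Small, fast 3-arm all-vs-all domain used across tests."""
    return DomainSpec(
        arms=[ArmSpec("A"), ArmSpec("B"), ArmSpec("C")],
        comparison="all_vs_all",
        direction="lower_better",
        stopping=StoppingRules(0.99, 0.01),
        allocation=AllocationRule(mode="rar", softening_gamma=0.5, min_allocation=0.10),
        first_look_n=100,
        look_interval_n=100,
        max_n=600,
        followup_days=5,
        data_verification_days=5,
    )


@pytest.fixture
def common_control_spec():
    """3-arm common-control domain with equivalence and futility rules."""
    return DomainSpec(
        arms=[ArmSpec("ctrl", is_control=True), ArmSpec("B"), ArmSpec("C")],
        comparison="common_control",
        direction="lower_better",
        stopping=StoppingRules(
            0.95,
            0.05,
            equivalence_margin=0.05,
            equivalence_prob_threshold=0.90,
            futility_margin=0.02,
            futility_prob_threshold=0.30,
            equivalence_vs_promoted_controls=True,
        ),
        allocation=AllocationRule(mode="fixed_sqrt_control"),
        first_look_n=100,
        look_interval_n=100,
        max_n=800,
        followup_days=5,
        data_verification_days=5,
    )


@pytest.fixture
def null_scenario():
    return Scenario((0.25, 0.25, 0.25), accrual_rate=20.0, label="null")
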