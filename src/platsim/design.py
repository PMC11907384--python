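"""Static specification of a platform-trial domain.

A *domain* is a set of comparable interventions randomised together within
the platform, analogous to a stand-alone multi-arm trial.  The guiding
outcome driving all adaptive decisions is binary (e.g. fixed-time
mortality); a ``direction`` flag says whether higher or lower event
probabilities are better, so mortality-type outcomes use ``lower_better``.

The classes here are plain frozen dataclasses validated by
:func:`validate_domain_spec`; YAML round-tripping is provided by
:func:`load_domain_config` / :func:`save_domain_config`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "ArmSpec",
    "StoppingRules",
    "AllocationRule",
    "DomainSpec",
    "Scenario",
    "ValidationError",
    "validate_domain_spec",
    "initial_allocation",
    "load_domain_config",
    "save_domain_config",
    "config_hash",
]

SPEC_VERSION = 1

ALLOCATION_MODES = ("fixed_equal", "fixed_sqrt_control", "rar", "rar_with_fixed_control")
COMPARISONS = ("all_vs_all", "common_control")
DIRECTIONS = ("higher_better", "lower_better")


class ValidationError(ValueError):
    """A domain specification violates one of its invariants."""


@dataclass(frozen=True)
class ArmSpec:
    """One arm of a domain.

    ``initial_allocation`` is either a probability in [0, 1] or the string
    ``"auto"``, resolved during validation from the comparison structure
    (equal split for all-vs-all, sqrt-ratio for common-control domains).
    """

    name: str
    is_control: bool = False
    initial_allocation: Union[float, str] = "auto"


@dataclass(frozen=True)
class StoppingRules:
    """Decision thresholds for the guiding-outcome adaptive analyses.

    Superiority/inferiority rules are mandatory; practical-equivalence and
    futility rules are optional (futility only in common-control domains).
    Margins are absolute risk differences.  All rules are binding.
    """

    superiority_threshold: float
    inferiority_threshold: float
    equivalence_margin: Optional[float] = None
    equivalence_prob_threshold: Optional[float] = None
    futility_margin: Optional[float] = None
    futility_prob_threshold: Optional[float] = None
    equivalence_vs_promoted_controls: bool = False

    @property
    def has_equivalence(self) -> bool:
        return (
            self.equivalence_margin is not None
            and self.equivalence_prob_threshold is not None
        )

    @property
    def has_futility(self) -> bool:
        return self.futility_margin is not None and self.futility_prob_threshold is not None


@dataclass(frozen=True)
class AllocationRule:
    """How allocation probabilities are set after each adaptive analysis.

    ``softening_gamma`` is the exponent of the power transform applied to
    the probabilities of each arm being overall best under
    response-adaptive randomisation (RAR); gamma = 0 gives equal
    allocation, gamma = 1 uses the raw probabilities.  ``min_allocation`` /
    ``max_allocation`` clip the resulting probabilities.
    """

    mode: str = "fixed_equal"
    softening_gamma: float = 1.0
    min_allocation: float = 0.0
    max_allocation: float = 1.0

    @property
    def is_rar(self) -> bool:
        return self.mode in ("rar", "rar_with_fixed_control")


@dataclass(frozen=True)
class DomainSpec:
    """The full static design of one domain.

    The outcome-data lag — follow-up duration of the guiding outcome plus a
    data collection/verification window (default 15 days) — gates entry of
    each patient into the adaptive analyses.  Adaptive analyses (*looks*)
    fire when the number of lag-complete patients reaches
    ``first_look_n``, then every ``look_interval_n`` thereafter, with a
    final analysis at ``max_n``.  The guiding-outcome prior is
    Beta(``prior_alpha``, ``prior_beta``).
    """

    arms: Sequence[ArmSpec]
    comparison: str
    direction: str
    stopping: StoppingRules
    allocation: AllocationRule
    first_look_n: int
    look_interval_n: int
    max_n: int
    followup_days: float
    data_verification_days: float = 15.0
    prior_alpha: float = 1.0
    prior_beta: float = 1.0
    name: str = "domain"

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    @property
    def arm_names(self) -> list[str]:
        return [a.name for a in self.arms]

    @property
    def control_index(self) -> Optional[int]:
        for i, a in enumerate(self.arms):
            if a.is_control:
                return i
        return None

    @property
    def outcome_lag_days(self) -> float:
        return self.followup_days + self.data_verification_days


@dataclass(frozen=True)
class Scenario:
    """True state of nature for a simulation batch.

    ``true_event_probs`` holds one guiding-outcome event probability per
    arm; a null scenario has identical probabilities in every arm.
    ``accrual_rate`` is the expected inclusion rate in patients/day.
    """

    true_event_probs: Sequence[float]
    accrual_rate: float
    label: str = "scenario"


# ---------------------------------------------------------------------------
# validation


def _fail(field_name: str, message: str) -> None:
    raise ValidationError(f"{field_name}: {message}")


def initial_allocation(
    n_arms: int, mode: str, control_index: Optional[int] = None
) -> np.ndarray:
    """Initial allocation probability vector for ``n_arms`` arms.

    ``fixed_equal`` (also the starting profile for RAR without a fixed
    control) splits equally.  ``fixed_sqrt_control`` (and RAR with a fixed
    control) gives the control a weight of sqrt(k) against 1 for each of
    the k non-control arms, the usual sqrt(k):1 ratio that roughly
    minimises the variance of the pairwise comparisons against a shared
    control.
    """
    if n_arms < 2:
        _fail("n_arms", "at least 2 arms required")
    if mode in ("fixed_equal", "rar"):
        return np.full(n_arms, 1.0 / n_arms)
    if mode in ("fixed_sqrt_control", "rar_with_fixed_control"):
        if control_index is None:
            _fail("control_index", f"mode {mode!r} requires a control arm index")
        k = n_arms - 1
        w = np.ones(n_arms)
        w[control_index] = math.sqrt(k)
        return w / w.sum()
    _fail("mode", f"unknown allocation mode {mode!r}")
    raise AssertionError  # unreachable


def validate_domain_spec(spec: DomainSpec) -> DomainSpec:
    """Validate every invariant of a :class:`DomainSpec` and resolve ``"auto"``
    initial allocations.

    Returns a spec identical to the input except that ``"auto"`` allocations
    are replaced by numbers; validating an already-validated spec returns an
    identical spec (idempotence).  Raises :class:`ValidationError` naming
    the offending field otherwise.
    """
    arms = list(spec.arms)
    if len(arms) < 2:
        _fail("arms", "a domain needs at least 2 arms")
    names = [a.name for a in arms]
    if len(set(names)) != len(names):
        _fail("arms", f"arm names must be unique, got {names}")
    n_controls = sum(a.is_control for a in arms)
    if n_controls > 1:
        _fail("arms", "at most one arm may be flagged is_control")

    if spec.comparison not in COMPARISONS:
        _fail("comparison", f"must be one of {COMPARISONS}")
    if spec.direction not in DIRECTIONS:
        _fail("direction", f"must be one of {DIRECTIONS}")
    if spec.comparison == "common_control" and n_controls != 1:
        _fail("comparison", "common_control requires exactly one control arm")

    st = spec.stopping
    if not (0.0 <= st.inferiority_threshold < st.superiority_threshold <= 1.0):
        _fail(
            "stopping",
            "need 0 <= inferiority_threshold < superiority_threshold <= 1, got "
            f"{st.inferiority_threshold} / {st.superiority_threshold}",
        )
    if (st.equivalence_margin is None) != (st.equivalence_prob_threshold is None):
        _fail("stopping", "equivalence_margin and equivalence_prob_threshold go together")
    if (st.futility_margin is None) != (st.futility_prob_threshold is None):
        _fail("stopping", "futility_margin and futility_prob_threshold go together")
    for label, margin in (("equivalence_margin", st.equivalence_margin),
                          ("futility_margin", st.futility_margin)):
        if margin is not None and margin < 0:
            _fail(f"stopping.{label}", "margins must be non-negative")
    for label, thr in (("equivalence_prob_threshold", st.equivalence_prob_threshold),
                       ("futility_prob_threshold", st.futility_prob_threshold)):
        if thr is not None and not (0.0 < thr < 1.0):
            _fail(f"stopping.{label}", "probability thresholds must lie in (0, 1)")
    if st.has_futility and spec.comparison != "common_control":
        _fail("stopping.futility_margin", "futility requires common control")

    al = spec.allocation
    if al.mode not in ALLOCATION_MODES:
        _fail("allocation.mode", f"must be one of {ALLOCATION_MODES}")
    if al.mode in ("fixed_sqrt_control", "rar_with_fixed_control") and n_controls == 0:
        _fail("allocation.mode", f"{al.mode!r} requires a control arm")
    if not (0.0 <= al.softening_gamma <= 1.0):
        _fail("allocation.softening_gamma", "must lie in [0, 1]")
    if not (0.0 <= al.min_allocation <= al.max_allocation <= 1.0):
        _fail("allocation", "need 0 <= min_allocation <= max_allocation <= 1")
    if al.min_allocation * len(arms) > 1.0 + 1e-12:
        _fail("allocation.min_allocation", "min_allocation * n_arms must be <= 1")
    if al.max_allocation * len(arms) < 1.0 - 1e-12:
        _fail("allocation.max_allocation", "max_allocation * n_arms must be >= 1")

    if spec.first_look_n < 1:
        _fail("first_look_n", "must be >= 1")
    if spec.look_interval_n < 1:
        _fail("look_interval_n", "must be >= 1")
    if spec.first_look_n > spec.max_n:
        _fail("first_look_n", "must not exceed max_n")
    if spec.outcome_lag_days <= 0:
        _fail("followup_days", "outcome-data lag (follow-up + verification) must be > 0")
    if spec.prior_alpha <= 0 or spec.prior_beta <= 0:
        _fail("prior_alpha", "prior hyperparameters must be positive")

    # resolve "auto" allocations and check the explicit ones
    auto_mode = (
        "fixed_equal" if spec.comparison == "all_vs_all" else "fixed_sqrt_control"
    )
    auto = initial_allocation(len(arms), auto_mode, spec.control_index)
    resolved: list[ArmSpec] = []
    explicit: list[tuple[int, float]] = []
    for i, a in enumerate(arms):
        if a.initial_allocation == "auto":
            resolved.append(dataclasses.replace(a, initial_allocation=float(auto[i])))
        else:
            try:
                p = float(a.initial_allocation)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                _fail(f"arms[{i}].initial_allocation", "must be a probability or 'auto'")
            if not (0.0 <= p <= 1.0):
                _fail(f"arms[{i}].initial_allocation", "must lie in [0, 1]")
            explicit.append((i, p))
            resolved.append(dataclasses.replace(a, initial_allocation=p))
    if len(explicit) == len(arms):
        total = sum(p for _, p in explicit)
        if abs(total - 1.0) > 1e-9:
            _fail("arms", f"explicit initial allocations must sum to 1, got {total}")
    elif explicit:
        _fail("arms", "initial allocations must be all explicit or all 'auto'")

    return dataclasses.replace(spec, arms=tuple(resolved))


def scenario_for(spec: DomainSpec, scenario: Scenario) -> Scenario:
    """Check a scenario against a domain spec."""
    probs = list(scenario.true_event_probs)
    if len(probs) != spec.n_arms:
        _fail("true_event_probs", f"expected {spec.n_arms} probabilities, got {len(probs)}")
    for p in probs:
        if not (0.0 < p < 1.0):
            _fail("true_event_probs", "probabilities must lie in (0, 1)")
    if scenario.accrual_rate <= 0:
        _fail("accrual_rate", "must be > 0")
    return scenario


# ---------------------------------------------------------------------------
# YAML round-trip


def _num(v):
    # canonicalise numeric types so equal designs serialise identically
    if isinstance(v, bool) or v is None or isinstance(v, str):
        return v
    if isinstance(v, (int, np.integer)):
        return float(v)
    if isinstance(v, (float, np.floating)):
        return float(v)
    return v


def _spec_to_dict(spec: DomainSpec) -> dict:
    d = {
        "spec_version": SPEC_VERSION,
        "name": spec.name,
        "comparison": spec.comparison,
        "direction": spec.direction,
        "arms": [
            {
                "name": a.name,
                "is_control": bool(a.is_control),
                "initial_allocation": _num(a.initial_allocation),
            }
            for a in spec.arms
        ],
        "stopping": {k: _num(v) for k, v in dataclasses.asdict(spec.stopping).items()},
        "allocation": {k: _num(v) for k, v in dataclasses.asdict(spec.allocation).items()},
        "first_look_n": int(spec.first_look_n),
        "look_interval_n": int(spec.look_interval_n),
        "max_n": int(spec.max_n),
        "followup_days": float(spec.followup_days),
        "data_verification_days": float(spec.data_verification_days),
        "prior_alpha": float(spec.prior_alpha),
        "prior_beta": float(spec.prior_beta),
    }
    return d


def _spec_from_dict(d: dict) -> tuple[DomainSpec, list[Scenario]]:
    version = d.get("spec_version", SPEC_VERSION)
    if version != SPEC_VERSION:
        raise ValidationError(f"spec_version: unsupported version {version}")
    arms = tuple(
        ArmSpec(
            name=str(a["name"]),
            is_control=bool(a.get("is_control", False)),
            initial_allocation=a.get("initial_allocation", "auto"),
        )
        for a in d["arms"]
    )
    spec = DomainSpec(
        arms=arms,
        comparison=d["comparison"],
        direction=d["direction"],
        stopping=StoppingRules(**d["stopping"]),
        allocation=AllocationRule(**d.get("allocation", {})),
        first_look_n=int(d["first_look_n"]),
        look_interval_n=int(d["look_interval_n"]),
        max_n=int(d["max_n"]),
        followup_days=float(d["followup_days"]),
        data_verification_days=float(d.get("data_verification_days", 15.0)),
        prior_alpha=float(d.get("prior_alpha", 1.0)),
        prior_beta=float(d.get("prior_beta", 1.0)),
        name=str(d.get("name", "domain")),
    )
    scenarios = [
        Scenario(
            true_event_probs=tuple(float(p) for p in s["true_event_probs"]),
            accrual_rate=float(s["accrual_rate"]),
            label=str(s.get("label", f"scenario-{i}")),
        )
        for i, s in enumerate(d.get("scenarios", []))
    ]
    return spec, scenarios


def load_domain_config(path: Union[str, Path]) -> tuple[DomainSpec, list[Scenario]]:
    """Read a domain configuration (and its scenarios) from YAML and validate it."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    spec, scenarios = _spec_from_dict(d)
    spec = validate_domain_spec(spec)
    for sc in scenarios:
        scenario_for(spec, sc)
    return spec, scenarios


def save_domain_config(
    spec: DomainSpec, path: Union[str, Path], scenarios: Sequence[Scenario] = ()
) -> None:
    """Write a domain configuration to YAML (lossless round-trip)."""
    d = _spec_to_dict(spec)
    if scenarios:
        d["scenarios"] = [
            {
                "label": s.label,
                "true_event_probs": [float(p) for p in s.true_event_probs],
                "accrual_rate": s.accrual_rate,
            }
            for s in scenarios
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_hash(spec: DomainSpec) -> str:
    """Deterministic sha256 of the canonicalised configuration.

    Logged with every simulation run so that any result can be traced to
    the exact design that produced it.
    """
    payload = json.dumps(_spec_to_dict(spec), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
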