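"""Arm dropping, domain stopping, and control promotion at an adaptive
analysis.

Two comparison structures are supported.  *All-vs-all* domains drop arms
whose probability of being overall best falls below the inferiority
threshold, stop for superiority when a single arm's probability of being
best exceeds the superiority threshold, and may stop for practical
equivalence when all remaining arms are within an absolute margin of each
other.  *Common-control* domains compare each non-control arm pairwise
against the control: arms are dropped for inferiority, equivalence, or
futility, and a non-control arm beating the control at the superiority
threshold is promoted to be the new control (the old control is dropped).

Whenever a pass drops an arm or replaces the control, the analysis is
immediately repeated on the reduced arm set, because the updated
probabilities may trigger further rules; :func:`iterate_to_fixpoint`
drives this loop.  All stopping rules are binding, and rule precedence
within a pass is superiority, then inferiority, then equivalence, then
futility, so the strongest conclusion wins.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .design import StoppingRules
from .posteriors import ProbabilityReport

__all__ = [
    "ArmStatus",
    "StatusChange",
    "LookDecision",
    "evaluate_look_all_vs_all",
    "evaluate_look_common_control",
    "iterate_to_fixpoint",
]


class ArmStatus(enum.IntEnum):
    """Life-cycle state of one arm.  Transitions are one-way."""

    ACTIVE = 0
    CONTROL = 1
    DROPPED_INFERIOR = 2
    DROPPED_EQUIVALENT = 3
    DROPPED_FUTILE = 4
    SUPERIOR = 5

    @property
    def in_play(self) -> bool:
        """Still being randomised and analysed."""
        return self in (ArmStatus.ACTIVE, ArmStatus.CONTROL)


@dataclass(frozen=True)
class StatusChange:
    """One arm's status change, with the probability and threshold that
    triggered it."""

    arm: int
    new_status: ArmStatus
    rule: str
    probability: float
    threshold: float


@dataclass
class LookDecision:
    """Outcome of one adaptive analysis (possibly several rule passes)."""

    changes: list[StatusChange] = field(default_factory=list)
    domain_stopped: bool = False
    stop_reason: str = "none"  # superiority | equivalence | inconclusive_max_n | none
    selected_arm: Optional[int] = None
    new_control: Optional[int] = None
    iterations: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.domain_stopped and self.stop_reason == "none":
            raise ValueError("a stopped domain needs a stop_reason")


def _as_pos(active: Sequence[int]) -> np.ndarray:
    a = np.asarray(active, dtype=int)
    if a.ndim != 1 or len(a) < 1:
        raise ValueError("active arm set must be a non-empty 1-D index list")
    return a


def evaluate_look_all_vs_all(
    report: ProbabilityReport, rules: StoppingRules, active: Sequence[int]
) -> LookDecision:
    """Single rule pass for a domain comparing all arms simultaneously.

    ``active`` maps the report's columns to original arm indices.
    Precedence: superiority stop, then inferiority drops, then an
    equivalence stop.  If every arm simultaneously falls below the
    inferiority threshold (possible only with inconsistent thresholds),
    the arm with the highest probability of being best is retained and
    the event is flagged degenerate.
    """
    active = _as_pos(active)
    p_best = np.asarray(report.p_best, dtype=float)
    if len(p_best) != len(active):
        raise ValueError("report and active arm set disagree on arm count")
    if len(active) < 2:
        raise ValueError("all-vs-all evaluation needs >= 2 active arms")
    dec = LookDecision(iterations=1)

    top = int(np.argmax(p_best))
    if p_best[top] > rules.superiority_threshold:
        dec.domain_stopped = True
        dec.stop_reason = "superiority"
        dec.selected_arm = int(active[top])
        dec.changes.append(
            StatusChange(
                int(active[top]), ArmStatus.SUPERIOR, "superiority",
                float(p_best[top]), rules.superiority_threshold,
            )
        )
        return dec

    inferior = np.flatnonzero(p_best < rules.inferiority_threshold)
    if len(inferior) == len(active):
        inferior = inferior[inferior != top]
        dec.degenerate = True
    for i in inferior:
        dec.changes.append(
            StatusChange(
                int(active[i]), ArmStatus.DROPPED_INFERIOR, "inferiority",
                float(p_best[i]), rules.inferiority_threshold,
            )
        )
    if len(dec.changes):
        return dec

    if rules.has_equivalence and report.p_all_equivalent is not None:
        p_eq = float(report.p_all_equivalent)
        if p_eq > rules.equivalence_prob_threshold:
            dec.domain_stopped = True
            dec.stop_reason = "equivalence"
    return dec


def evaluate_look_common_control(
    report: ProbabilityReport,
    rules: StoppingRules,
    active: Sequence[int],
    control: int,
    control_is_original: bool = True,
) -> LookDecision:
    """Single rule pass for a domain with pairwise comparisons against a
    common control.

    ``control`` is the original-index control arm, which must be in
    ``active``.  All decisions of the pass are applied simultaneously;
    promotion replaces the control with the superior arm having the
    highest probability of being overall best (lowest index on ties) and
    drops the old control.  Equivalence and futility drops are assessed
    against promoted controls only when the rules allow it.
    """
    active = _as_pos(active)
    if control not in active:
        raise ValueError(f"control arm {control} is not active")
    if len(active) < 2:
        raise ValueError("common-control evaluation needs the control plus >= 1 arm")
    cpos = int(np.flatnonzero(active == control)[0])
    p_vs_c = np.asarray(report.p_better_than_control, dtype=float)
    p_best = np.asarray(report.p_best, dtype=float)
    if len(p_vs_c) != len(active):
        raise ValueError("report and active arm set disagree on arm count")

    dec = LookDecision(iterations=1)
    noncontrol = np.flatnonzero(active != control)
    decided: set[int] = set()

    # superiority -> promotion
    superior = [i for i in noncontrol if p_vs_c[i] > rules.superiority_threshold]
    if superior:
        order = sorted(superior, key=lambda i: (-p_best[i], active[i]))
        winner = order[0]
        dec.new_control = int(active[winner])
        dec.changes.append(
            StatusChange(
                int(active[winner]), ArmStatus.CONTROL, "superiority_promotion",
                float(p_vs_c[winner]), rules.superiority_threshold,
            )
        )
        dec.changes.append(
            StatusChange(
                int(active[cpos]), ArmStatus.DROPPED_INFERIOR, "control_replaced",
                float(p_vs_c[winner]), rules.superiority_threshold,
            )
        )
        decided.update({winner, cpos})

    # inferiority
    for i in noncontrol:
        if i in decided:
            continue
        if p_vs_c[i] < rules.inferiority_threshold:
            dec.changes.append(
                StatusChange(
                    int(active[i]), ArmStatus.DROPPED_INFERIOR, "inferiority",
                    float(p_vs_c[i]), rules.inferiority_threshold,
                )
            )
            decided.add(i)

    assess_optional = control_is_original or rules.equivalence_vs_promoted_controls

    # practical equivalence with the control
    if rules.has_equivalence and assess_optional and report.p_all_equivalent is not None:
        p_eq = np.asarray(report.p_all_equivalent, dtype=float)
        for i in noncontrol:
            if i in decided:
                continue
            if p_eq[i] > rules.equivalence_prob_threshold:
                dec.changes.append(
                    StatusChange(
                        int(active[i]), ArmStatus.DROPPED_EQUIVALENT, "equivalence",
                        float(p_eq[i]), rules.equivalence_prob_threshold,
                    )
                )
                decided.add(i)

    # futility: not superior to the control by the futility margin
    if rules.has_futility and assess_optional and report.p_futility_superior is not None:
        p_fut = np.asarray(report.p_futility_superior, dtype=float)
        for i in noncontrol:
            if i in decided:
                continue
            if p_fut[i] < rules.futility_prob_threshold:
                dec.changes.append(
                    StatusChange(
                        int(active[i]), ArmStatus.DROPPED_FUTILE, "futility",
                        float(p_fut[i]), rules.futility_prob_threshold,
                    )
                )
                decided.add(i)

    return dec


ReportFn = Callable[[np.ndarray, Optional[int]], ProbabilityReport]


def iterate_to_fixpoint(
    statuses: Sequence[ArmStatus],
    rules: StoppingRules,
    comparison: str,
    report_fn: ReportFn,
    original_control: Optional[int] = None,
) -> tuple[LookDecision, list[ArmStatus], list[dict]]:
    """Repeat rule passes on the shrinking arm set until nothing changes.

    ``report_fn(active_indices, control_pos)`` recomputes the posterior
    probability report for the given active arms (``control_pos`` is the
    control's position within them, or None for all-vs-all).  Returns the
    aggregated decision, the updated statuses, and a per-pass audit list.
    Termination is guaranteed: every pass either stops the domain,
    removes at least one arm, or makes no change.
    """
    statuses = list(statuses)
    n_arms = len(statuses)
    agg = LookDecision()
    audit: list[dict] = []

    for _ in range(n_arms + 1):
        active = np.flatnonzero([s.in_play for s in statuses])
        if len(active) == 1:
            agg.domain_stopped = True
            agg.stop_reason = "superiority"
            agg.selected_arm = int(active[0])
            statuses[int(active[0])] = ArmStatus.SUPERIOR
            break
        control = None
        if comparison == "common_control":
            ctl = [i for i in active if statuses[i] == ArmStatus.CONTROL]
            if len(ctl) != 1:
                raise RuntimeError("common-control domain lost its control arm")
            control = ctl[0]
        cpos = None if control is None else int(np.flatnonzero(active == control)[0])
        report = report_fn(active, cpos)

        if comparison == "all_vs_all":
            dec = evaluate_look_all_vs_all(report, rules, active)
        else:
            dec = evaluate_look_common_control(
                report, rules, active, control,
                control_is_original=(control == original_control),
            )
        agg.iterations += 1
        agg.degenerate = agg.degenerate or dec.degenerate
        audit.append(
            {
                "active": [int(i) for i in active],
                "control": None if control is None else int(control),
                "report": report.to_json_dict(),
                "changes": [
                    {
                        "arm": c.arm,
                        "new_status": c.new_status.name.lower(),
                        "rule": c.rule,
                        "probability": c.probability,
                        "threshold": c.threshold,
                    }
                    for c in dec.changes
                ],
                "stopped": dec.domain_stopped,
                "stop_reason": dec.stop_reason,
            }
        )
        for c in dec.changes:
            statuses[c.arm] = c.new_status
        agg.changes.extend(dec.changes)
        if dec.new_control is not None:
            agg.new_control = dec.new_control
        if dec.domain_stopped:
            agg.domain_stopped = True
            agg.stop_reason = dec.stop_reason
            agg.selected_arm = dec.selected_arm
            break
        if not dec.changes:
            break

    return agg, statuses, audit
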