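"""Patient accrual, outcome-data lag, and look scheduling.

Accrual is modelled as a homogeneous Poisson process.  A patient enters
the adaptive analyses only once their outcome-data lag (guiding-outcome
follow-up plus the data collection/verification window) has elapsed;
patients with outcome data available who have not completed the lag are
not analysed.  An adaptive analysis (*look*) fires the instant a
pre-specified number of patients has completed the lag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "PatientRecord",
    "LookSchedule",
    "build_look_schedule",
    "simulate_accrual",
    "analysis_ready_set",
    "next_look_trigger",
]


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient.

    ``lag_complete_day`` = arrival_day + follow-up + verification window;
    ``period`` is the time-period index in force at randomisation (a new
    period starts after every adaptation event).
    """

    id: int
    arrival_day: float
    arm: int
    event: int
    lag_complete_day: float
    period: int


@dataclass(frozen=True)
class LookSchedule:
    """Lag-complete patient counts at which adaptive analyses fire."""

    trigger_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        t = self.trigger_counts
        if not t:
            raise ValueError("trigger_counts must be non-empty")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("trigger_counts must be strictly increasing")

    @property
    def n_looks(self) -> int:
        return len(self.trigger_counts)


def build_look_schedule(first_look_n: int, look_interval_n: int, max_n: int) -> LookSchedule:
    """Triggers at first_look_n, +interval, ... capped at max_n.

    A final analysis at max_n is always scheduled (appended when max_n is
    not on the grid) so that inconclusiveness is only declared once the
    complete data have been analysed.
    """
    counts = list(range(first_look_n, max_n + 1, look_interval_n))
    if not counts or counts[-1] != max_n:
        counts.append(max_n)
    return LookSchedule(trigger_counts=tuple(counts))


def simulate_accrual(
    n: int, accrual_rate: float, rng: Union[int, np.random.Generator]
) -> np.ndarray:
    """Arrival days of ``n`` patients under Poisson-process accrual.

    Inter-arrival times are exponential with mean 1/``accrual_rate``
    (patients/day); the returned vector is the non-decreasing cumulative
    sum.  Deterministic given the seed/generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if accrual_rate <= 0:
        raise ValueError("accrual_rate must be > 0")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    gaps = gen.exponential(scale=1.0 / accrual_rate, size=n)
    return np.cumsum(gaps)


def analysis_ready_set(
    patients: Sequence[PatientRecord], calendar_day: float, n_arms: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-arm (events, totals) among patients whose lag has completed.

    A patient with ``lag_complete_day`` exactly equal to ``calendar_day``
    is included.  Totals sum to the number of lag-complete patients.
    """
    if n_arms is None:
        n_arms = max((p.arm for p in patients), default=-1) + 1
    events = np.zeros(n_arms, dtype=np.int64)
    totals = np.zeros(n_arms, dtype=np.int64)
    for p in patients:
        if p.lag_complete_day <= calendar_day:
            totals[p.arm] += 1
            events[p.arm] += p.event
    return events, totals


def tally_first(arms: np.ndarray, events: np.ndarray, upto: int, n_arms: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-arm (events, totals) over the first ``upto`` patients.

    Used by the engine, where patients are kept in arrival order so the
    analysis-ready set at a look is exactly the first ``trigger`` patients.
    """
    a = arms[:upto]
    totals = np.bincount(a, minlength=n_arms)
    ev = np.bincount(a, weights=events[:upto], minlength=n_arms)
    return ev.astype(np.int64), totals.astype(np.int64)


def next_look_trigger(schedule: LookSchedule, n_lag_complete: int, looks_done: int) -> bool:
    """Whether an adaptive analysis fires now.

    Fires iff the number of lag-complete patients has reached the next
    scheduled trigger; beyond the schedule it never fires (the maximum
    sample size handling takes over).
    """
    if looks_done < 0:
        raise ValueError("looks_done must be >= 0")
    if looks_done >= schedule.n_looks:
        return False
    return n_lag_complete >= schedule.trigger_counts[looks_done]
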