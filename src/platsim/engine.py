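"""Single-trial simulation, batch evaluation, and threshold calibration.

:func:`run_trial` simulates one domain end to end: Poisson accrual,
stratified-block then simple randomisation, Bernoulli guiding outcomes,
lag-gated adaptive analyses, arm dropping/stopping/promotion, and
allocation updates, until a stopping rule fires or the maximum sample
size is reached and analysed, after which every randomised participant
is included in the final analysis.  :func:`run_batch` aggregates
operating characteristics over independent replicate trials, and
:func:`calibrate_superiority_threshold` searches for the stopping
threshold that keeps the probability of a superiority stop under a null
scenario at or below a target (the design's type-1 error for the
guiding outcome).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .accrual import build_look_schedule, simulate_accrual, tally_first
from .adaptation import ArmStatus, iterate_to_fixpoint
from .allocation import AllocationState, rar_probabilities, rescale_fixed
from .design import (
    DomainSpec,
    Scenario,
    config_hash,
    scenario_for,
    validate_domain_spec,
)
from .posteriors import (
    PosteriorSet,
    ProbabilityReport,
    prob_all_equivalent,
    prob_best,
    prob_pairwise_better,
)

__all__ = [
    "TrialResult",
    "PerformanceMetrics",
    "CalibrationResult",
    "CalibrationError",
    "run_trial",
    "run_batch",
    "summarise_metrics",
    "calibrate_superiority_threshold",
    "write_results_jsonl",
]

SeedLike = Union[int, tuple, np.random.SeedSequence, np.random.Generator]

# entropy-stream tag for validation batches, kept distinct from the
# calibration stream derived from the same master seed
_FRESH_STREAM = 1_000_003


def _generator(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(seed))


@dataclass
class TrialResult:
    """Outcome of one simulated trial."""

    stop_reason: str  # superiority | equivalence | inconclusive_max_n
    selected_arm: Optional[int]
    n_randomised: int
    n_per_arm: np.ndarray
    events_per_arm: np.ndarray
    looks_done: int
    final_alpha: np.ndarray
    final_beta: np.ndarray
    final_posterior_median: np.ndarray
    statuses: list[ArmStatus]
    n_periods: int
    seed: Optional[tuple] = None
    config_hash: str = ""
    audit: list = field(default_factory=list)
    patients: Optional["pd.DataFrame"] = None  # per-patient log (opt-in)

    def __post_init__(self) -> None:
        if (self.selected_arm is not None) != (self.stop_reason == "superiority"):
            raise ValueError("selected_arm must be set iff the stop was for superiority")


@dataclass
class PerformanceMetrics:
    """Operating characteristics aggregated over a simulation batch."""

    n_sims: int
    p_conclusive: float
    p_superiority_stop: float
    p_equivalence_stop: float
    p_select_arm: np.ndarray
    expected_n: float
    sd_n: float
    mean_looks: float
    prop_allocated_best: float
    rmse_event_prob: Optional[float]

    def to_json_dict(self) -> dict:
        return {
            "n_sims": self.n_sims,
            "p_conclusive": self.p_conclusive,
            "p_superiority_stop": self.p_superiority_stop,
            "p_equivalence_stop": self.p_equivalence_stop,
            "p_select_arm": [float(p) for p in self.p_select_arm],
            "expected_n": self.expected_n,
            "sd_n": self.sd_n,
            "mean_looks": self.mean_looks,
            "prop_allocated_best": self.prop_allocated_best,
            "rmse_event_prob": self.rmse_event_prob,
        }


@dataclass
class CalibrationResult:
    """Outcome of a superiority-threshold calibration."""

    superiority_threshold: float
    inferiority_threshold: float
    achieved_type1: float
    mc_ci: tuple[float, float]
    n_sims: int
    seed: int
    trace: list[tuple[float, float]]
    config_hash: str = ""


class CalibrationError(RuntimeError):
    """The type-1 error target cannot be met within the threshold bounds."""


def _fixed_control_prob(n_active: int) -> float:
    k = n_active - 1
    return float(np.sqrt(k) / (np.sqrt(k) + k))


def run_trial(
    spec: DomainSpec,
    scenario: Scenario,
    seed: SeedLike,
    *,
    n_draws: int = 10_000,
    n_sites: int = 10,
    keep_audit: bool = True,
    keep_patients: bool = False,
) -> TrialResult:
    """Simulate one trial of ``spec`` under ``scenario``.

    Fully reproducible: the same (spec, scenario, seed) triple replays the
    identical trial bit for bit.  ``n_draws`` posterior draws are shared
    by all probability computations at a look; ``n_sites`` is the number
    of equally sized site strata used by block randomisation before the
    first adaptive analysis.
    """
    spec = validate_domain_spec(spec)
    scenario_for(spec, scenario)
    rng = _generator(seed)
    n_arms = spec.n_arms
    max_n = spec.max_n
    p_true = np.asarray(scenario.true_event_probs, dtype=float)
    rules = spec.stopping
    lag = spec.outcome_lag_days

    arrivals = simulate_accrual(max_n, scenario.accrual_rate, rng)
    sites = rng.integers(0, n_sites, size=max_n)
    u_outcome = rng.random(max_n)
    schedule = build_look_schedule(spec.first_look_n, spec.look_interval_n, max_n)

    statuses = [
        ArmStatus.CONTROL if a.is_control else ArmStatus.ACTIVE for a in spec.arms
    ]
    original_control = spec.control_index
    init_probs = np.array([float(a.initial_allocation) for a in spec.arms])
    alloc = AllocationState(probs=init_probs)

    arms = np.full(max_n, -1, dtype=int)
    events = np.zeros(max_n, dtype=np.int64)
    periods = np.zeros(max_n, dtype=np.int64)
    ev_c = np.zeros(n_arms, dtype=np.int64)
    tot_c = np.zeros(n_arms, dtype=np.int64)

    n_assigned = 0
    period = 0
    looks_done = 0
    stopped = False
    stop_reason = "inconclusive_max_n"
    selected: Optional[int] = None
    audit: list = []

    def make_report(active: np.ndarray, cpos: Optional[int]) -> ProbabilityReport:
        post = PosteriorSet(
            alpha=spec.prior_alpha + ev_c[active].astype(float),
            beta=spec.prior_beta + (tot_c[active] - ev_c[active]).astype(float),
            direction=spec.direction,
        )
        draws = post.sample(n_draws, rng)
        rep = ProbabilityReport(p_best=prob_best(draws, spec.direction), n_draws=n_draws)
        if spec.comparison == "common_control":
            rep.p_better_than_control = prob_pairwise_better(
                draws, cpos, 0.0, spec.direction
            )
            if rules.has_futility:
                rep.p_futility_superior = prob_pairwise_better(
                    draws, cpos, rules.futility_margin, spec.direction
                )
            if rules.has_equivalence:
                rep.p_all_equivalent = prob_all_equivalent(
                    draws, rules.equivalence_margin, "vs_control", cpos
                )
        elif rules.has_equivalence:
            rep.p_all_equivalent = prob_all_equivalent(
                draws, rules.equivalence_margin, "all_vs_all"
            )
        return rep

    for trigger in schedule.trigger_counts:
        look_day = arrivals[trigger - 1] + lag
        n_enrolled = int(np.searchsorted(arrivals, look_day, side="right"))
        n_enrolled = min(max(n_enrolled, trigger), max_n)
        if n_enrolled > n_assigned:
            sl = slice(n_assigned, n_enrolled)
            if alloc.phase == "simple":
                cum = np.cumsum(alloc.probs)
                new_arms = np.searchsorted(
                    cum, rng.random(n_enrolled - n_assigned), side="right"
                )
            else:
                from .allocation import assign_arm

                new_arms = np.array(
                    [assign_arm(alloc, s, rng) for s in sites[sl]], dtype=int
                )
            arms[sl] = new_arms
            events[sl] = u_outcome[sl] < p_true[new_arms]
            periods[sl] = period
            n_assigned = n_enrolled

        ev_c[:], tot_c[:] = tally_first(arms, events, trigger, n_arms)
        decision, statuses, passes = iterate_to_fixpoint(
            statuses, rules, spec.comparison, make_report, original_control
        )
        looks_done += 1
        if keep_audit:
            audit.append(
                {
                    "look": looks_done,
                    "trigger": int(trigger),
                    "n_randomised": int(n_assigned),
                    "n_analysed_per_arm": tot_c.tolist(),
                    "events_per_arm": ev_c.tolist(),
                    "passes": passes,
                    "allocation_before": alloc.probs.tolist(),
                    "stopped": decision.domain_stopped,
                    "stop_reason": decision.stop_reason,
                }
            )
        if decision.domain_stopped:
            stopped = True
            stop_reason = decision.stop_reason
            selected = decision.selected_arm
            break

        # allocation update after the look; the first look also ends the
        # stratified-block phase
        active = np.flatnonzero([s.in_play for s in statuses])
        control = None
        if spec.comparison == "common_control":
            control = next(
                i for i in active if statuses[i] == ArmStatus.CONTROL
            )
        if spec.allocation.is_rar:
            final_pass = passes[-1]
            p_best_active = np.asarray(final_pass["report"]["p_best"], dtype=float)
            pass_active = np.asarray(final_pass["active"], dtype=int)
            new_probs = np.zeros(n_arms)
            if spec.allocation.mode == "rar_with_fixed_control":
                cpos = int(np.flatnonzero(pass_active == control)[0])
                sub = rar_probabilities(
                    p_best_active,
                    spec.allocation,
                    control=cpos,
                    control_prob=_fixed_control_prob(len(pass_active)),
                )
            else:
                sub = rar_probabilities(p_best_active, spec.allocation)
            new_probs[pass_active] = sub
        else:
            new_probs = rescale_fixed(spec, active, control)

        alloc_changed = not np.allclose(new_probs, alloc.probs, atol=1e-12)
        if looks_done == 1:
            alloc.switch_to_simple()
        if alloc_changed:
            alloc.set_probs(new_probs)
        if alloc_changed or decision.changes:
            period += 1

        if keep_audit:
            audit[-1]["allocation_after"] = alloc.probs.tolist()
            audit[-1]["period_after"] = period

    # final analysis: all randomised participants are followed up
    ev_f, tot_f = tally_first(arms, events, n_assigned, n_arms)
    final_alpha = spec.prior_alpha + ev_f.astype(float)
    final_beta = spec.prior_beta + (tot_f - ev_f).astype(float)
    final_median = stats.beta.ppf(0.5, final_alpha, final_beta)

    patient_log = None
    if keep_patients:
        patient_log = pd.DataFrame(
            {
                "id": np.arange(n_assigned),
                "arrival_day": arrivals[:n_assigned],
                "site": sites[:n_assigned],
                "arm": arms[:n_assigned],
                "event": events[:n_assigned],
                "lag_complete_day": arrivals[:n_assigned] + lag,
                "period": periods[:n_assigned],
            }
        )

    seed_tag = seed if isinstance(seed, (int, tuple)) else None
    return TrialResult(
        stop_reason=stop_reason,
        selected_arm=selected,
        n_randomised=int(n_assigned),
        n_per_arm=tot_f,
        events_per_arm=ev_f,
        looks_done=looks_done,
        final_alpha=final_alpha,
        final_beta=final_beta,
        final_posterior_median=final_median,
        statuses=list(statuses),
        n_periods=period + 1,
        seed=(seed_tag,) if isinstance(seed_tag, int) else seed_tag,
        config_hash=config_hash(spec),
        audit=audit,
        patients=patient_log,
    )


def summarise_metrics(
    results: Sequence[TrialResult], scenario: Scenario, direction: str
) -> PerformanceMetrics:
    """Aggregate a batch of trial results into performance metrics.

    The *truly best* arm(s) attain the extreme true event probability
    under ``direction``; exact ties all count as best when computing the
    proportion of patients allocated to the best arm.  The RMSE is over
    the selected arm's final posterior median vs its true event
    probability, among trials that selected an arm (None if none did).
    """
    if not results:
        raise ValueError("results must be non-empty")
    p_true = np.asarray(scenario.true_event_probs, dtype=float)
    n_arms = len(p_true)
    best_val = p_true.min() if direction == "lower_better" else p_true.max()
    best_arms = np.flatnonzero(p_true == best_val)

    n = len(results)
    reasons = [r.stop_reason for r in results]
    p_sup = sum(r == "superiority" for r in reasons) / n
    p_eq = sum(r == "equivalence" for r in reasons) / n
    select = np.zeros(n_arms)
    errors = []
    n_rand = np.array([r.n_randomised for r in results], dtype=float)
    looks = np.array([r.looks_done for r in results], dtype=float)
    prop_best = np.empty(n)
    for i, r in enumerate(results):
        prop_best[i] = r.n_per_arm[best_arms].sum() / r.n_randomised
        if r.selected_arm is not None:
            select[r.selected_arm] += 1
            errors.append(r.final_posterior_median[r.selected_arm] - p_true[r.selected_arm])
    rmse = float(np.sqrt(np.mean(np.square(errors)))) if errors else None
    return PerformanceMetrics(
        n_sims=n,
        p_conclusive=p_sup + p_eq,
        p_superiority_stop=p_sup,
        p_equivalence_stop=p_eq,
        p_select_arm=select / n,
        expected_n=float(n_rand.mean()),
        sd_n=float(n_rand.std(ddof=1)) if n > 1 else 0.0,
        mean_looks=float(looks.mean()),
        prop_allocated_best=float(prop_best.mean()),
        rmse_event_prob=rmse,
    )


def run_batch(
    spec: DomainSpec,
    scenario: Scenario,
    n_sims: int,
    seed: Union[int, tuple],
    *,
    n_draws: int = 10_000,
    n_sites: int = 10,
    keep_audit: bool = False,
    n_jobs: int = 1,
) -> tuple[list[TrialResult], PerformanceMetrics]:
    """Run ``n_sims`` independent trials and summarise them.

    Trial *i* uses the seed stream ``(seed, i)``, so results are
    identical regardless of worker count and any single trial can be
    replayed in isolation with ``run_trial(spec, scenario, (seed, i))``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    spec = validate_domain_spec(spec)

    base = tuple(seed) if isinstance(seed, tuple) else (seed,)

    def one(i: int) -> TrialResult:
        return run_trial(
            spec,
            scenario,
            (*base, i),
            n_draws=n_draws,
            n_sites=n_sites,
            keep_audit=keep_audit,
        )

    if n_jobs == 1:
        results = [one(i) for i in range(n_sims)]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one)(i) for i in range(n_sims))
    metrics = summarise_metrics(results, scenario, spec.direction)
    return results, metrics


def calibrate_superiority_threshold(
    spec: DomainSpec,
    null_scenario: Scenario,
    target: float = 0.05,
    n_sims: int = 2_000,
    tol: float = 0.005,
    seed: int = 0,
    *,
    bounds: tuple[float, float] = (0.95, 0.9995),
    pin_inferiority: Optional[float] = None,
    n_draws: int = 10_000,
    n_sites: int = 10,
    n_jobs: int = 1,
) -> CalibrationResult:
    """Calibrate the superiority threshold to a type-1-error target.

    Type-1 error is the probability of a superiority stop under the null
    scenario (identical true event probabilities in all arms); stops for
    practical equivalence under the null are correct conclusions, not
    errors.  The inferiority threshold tracks ``1 - superiority`` unless
    ``pin_inferiority`` holds it fixed.  Bisection over the threshold
    uses the *same* per-trial seed streams for every candidate (common
    random numbers), which makes the estimated error curve monotone in
    practice; the returned threshold is the smallest examined value whose
    estimated error is at or below the target on that common batch.
    Raises :class:`CalibrationError` if even the upper bound exceeds the
    target.
    """
    spec = validate_domain_spec(spec)
    p = set(null_scenario.true_event_probs)
    if len(p) != 1:
        raise ValueError("calibration requires a null scenario (identical arm probabilities)")
    if not (0.0 < target < 1.0):
        raise ValueError("target must lie in (0, 1)")

    trace: list[tuple[float, float]] = []

    def type1(threshold: float) -> float:
        inf = 1.0 - threshold if pin_inferiority is None else pin_inferiority
        rules = dataclasses.replace(
            spec.stopping,
            superiority_threshold=threshold,
            inferiority_threshold=inf,
        )
        trial_spec = dataclasses.replace(spec, stopping=rules)
        _, metrics = run_batch(
            trial_spec,
            null_scenario,
            n_sims,
            seed,
            n_draws=n_draws,
            n_sites=n_sites,
            n_jobs=n_jobs,
        )
        trace.append((threshold, metrics.p_superiority_stop))
        return metrics.p_superiority_stop

    lo, hi = bounds
    err_hi = type1(hi)
    if err_hi > target:
        raise CalibrationError(
            f"type-1 error {err_hi:.4f} at upper threshold bound {hi} exceeds target {target}"
        )
    err_lo = type1(lo)
    if err_lo <= target:
        hi, err_hi = lo, err_lo
    else:
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            err_mid = type1(mid)
            if err_mid <= target:
                hi, err_hi = mid, err_mid
            else:
                lo = mid

    se = float(np.sqrt(max(err_hi * (1 - err_hi), 1e-12) / n_sims))
    return CalibrationResult(
        superiority_threshold=hi,
        inferiority_threshold=(1.0 - hi if pin_inferiority is None else pin_inferiority),
        achieved_type1=err_hi,
        mc_ci=(max(0.0, err_hi - 1.96 * se), min(1.0, err_hi + 1.96 * se)),
        n_sims=n_sims,
        seed=seed,
        trace=trace,
        config_hash=config_hash(spec),
    )


def fresh_validation_seed(seed: int) -> tuple:
    """A seed stream for validation batches, disjoint from calibration."""
    return (seed, _FRESH_STREAM)


def write_results_jsonl(results: Sequence[TrialResult], path) -> None:
    """Write per-trial result summaries as JSON lines (gzipped for ``.gz``).

    One line per trial: stop reason, selected arm, per-arm sample sizes and
    events, looks, periods, seed, and config hash — enough to re-derive the
    batch metrics and replay any single trial.
    """
    import gzip
    import json

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in results:
            fh.write(
                json.dumps(
                    {
                        "stop_reason": r.stop_reason,
                        "selected_arm": r.selected_arm,
                        "n_randomised": r.n_randomised,
                        "n_per_arm": r.n_per_arm.tolist(),
                        "events_per_arm": r.events_per_arm.tolist(),
                        "looks_done": r.looks_done,
                        "n_periods": r.n_periods,
                        "seed": list(r.seed) if r.seed else None,
                        "config_hash": r.config_hash,
                    }
                )
                + "\n"
            )
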