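"""Allocation probabilities and randomisation of incoming patients.

Allocation probabilities are refreshed only at adaptive analyses: fixed
profiles are rescaled over the surviving arms, and response-adaptive
randomisation (RAR) maps the probabilities of each arm being overall
best through a softening power transform with optional minimum/maximum
limits.  Before the first adaptive analysis patients are randomised with
permuted blocks stratified by site; afterwards with simple, unstratified
randomisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, Optional, Sequence, Union

import numpy as np

from .design import AllocationRule, DomainSpec, initial_allocation

__all__ = [
    "AllocationState",
    "rescale_fixed",
    "rar_probabilities",
    "assign_arm",
    "assign_batch",
]

_EPS = 1e-12


def rescale_fixed(
    spec: DomainSpec, active: Sequence[int], control: Optional[int] = None
) -> np.ndarray:
    """Rescaled fixed allocation over the active arms (full-length vector).

    ``fixed_equal`` splits equally among the active arms;
    ``fixed_sqrt_control`` recomputes the sqrt(k):1 control ratio with k
    the current number of active non-control arms.  Dropped arms get 0.
    """
    active = np.asarray(active, dtype=int)
    if len(active) < 2:
        raise ValueError("rescaling needs >= 2 active arms")
    probs = np.zeros(spec.n_arms)
    mode = spec.allocation.mode
    if mode in ("fixed_equal", "rar"):
        probs[active] = 1.0 / len(active)
        return probs
    if mode in ("fixed_sqrt_control", "rar_with_fixed_control"):
        if control is None or control not in active:
            raise ValueError("control-based rescaling requires an active control index")
        sub = initial_allocation(
            len(active), "fixed_sqrt_control",
            int(np.flatnonzero(active == control)[0]),
        )
        probs[active] = sub
        return probs
    raise ValueError(f"unknown allocation mode {mode!r}")


def _clip_renormalise(
    weights: np.ndarray, lo: float, hi: float, total: float
) -> np.ndarray:
    """Proportional allocation of ``total`` mass with per-arm limits.

    Violators are clipped to the limit and the unclipped arms share the
    remaining mass proportionally; repeated until feasible.
    """
    n = len(weights)
    if lo * n > total + 1e-9 or hi * n < total - 1e-9:
        raise ValueError(
            f"infeasible limits: {n} arms, mass {total}, min {lo}, max {hi}"
        )
    out = np.empty(n)
    fixed = np.zeros(n, dtype=bool)
    for _ in range(n + 1):
        free = ~fixed
        if not free.any():
            break
        rem = total - out[fixed].sum()
        w = weights[free]
        if w.sum() <= _EPS:
            p = np.full(free.sum(), rem / free.sum())
        else:
            p = w / w.sum() * rem
        too_lo = p < lo - 1e-12
        too_hi = p > hi + 1e-12
        if not (too_lo.any() or too_hi.any()):
            out[free] = p
            return out
        idx = np.flatnonzero(free)
        out[idx[too_lo]] = lo
        out[idx[too_hi]] = hi
        fixed[idx[too_lo]] = True
        fixed[idx[too_hi]] = True
    if abs(out.sum() - total) > 1e-9:
        raise ValueError("infeasible min/max allocation limits")
    return out


def rar_probabilities(
    p_best: np.ndarray,
    rule: AllocationRule,
    control: Optional[int] = None,
    control_prob: Optional[float] = None,
) -> np.ndarray:
    """Response-adaptive allocation over the active arms.

    Raw weights are ``p_best ** softening_gamma`` (gamma = 0 gives equal
    allocation, gamma = 1 the raw probabilities of being best); with a
    fixed control (index ``control``) the control receives exactly
    ``control_prob`` and the transform is applied to the non-control arms
    over the remaining mass.  Min/max limits are enforced by clipping and
    proportional renormalisation of the unclipped arms.
    """
    p_best = np.asarray(p_best, dtype=float)
    if p_best.ndim != 1 or len(p_best) < 2:
        raise ValueError("p_best must be a vector over >= 2 active arms")
    if np.any(p_best < -_EPS) or abs(np.nansum(p_best) - 1.0) > 1e-6:
        raise ValueError("p_best must be non-negative and sum to 1")
    out = np.empty_like(p_best)
    if control is not None:
        if control_prob is None:
            raise ValueError("a fixed control needs control_prob")
        mask = np.ones(len(p_best), dtype=bool)
        mask[control] = False
        w = np.power(p_best[mask], rule.softening_gamma)
        out[control] = control_prob
        out[mask] = _clip_renormalise(
            w, rule.min_allocation, rule.max_allocation, 1.0 - control_prob
        )
    else:
        w = np.power(p_best, rule.softening_gamma)
        out[:] = _clip_renormalise(w, rule.min_allocation, rule.max_allocation, 1.0)
    return out


@dataclass
class AllocationState:
    """Allocation probabilities in force plus the block-randomisation state.

    ``probs`` is a full-length vector over all arms (dropped arms have
    probability exactly 0).  In the ``stratified_block`` phase each site
    stratum holds a permuted block realising the allocation ratio; the
    phase switches to ``simple`` at the first adaptive analysis and never
    switches back (pending blocks are discarded).
    """

    probs: np.ndarray
    phase: str = "stratified_block"  # or "simple"
    block_min: Optional[int] = None  # default 2 x number of in-play arms
    buffers: Dict[Hashable, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if abs(self.probs.sum() - 1.0) > 1e-9 or np.any(self.probs < -_EPS):
            raise ValueError("allocation probabilities must be non-negative and sum to 1")

    def set_probs(self, probs: np.ndarray) -> None:
        probs = np.asarray(probs, dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < -_EPS):
            raise ValueError("allocation probabilities must be non-negative and sum to 1")
        self.probs = probs
        self.buffers.clear()

    def switch_to_simple(self) -> None:
        """Discard pending blocks and use simple randomisation from now on."""
        self.phase = "simple"
        self.buffers.clear()


def _block_size(probs: np.ndarray, minimum: int) -> int:
    # smallest multiple-of-denominator block >= minimum when the ratio is
    # rational with a small denominator; otherwise the minimum itself
    for size in range(minimum, 8 * minimum + 1):
        q = probs * size
        if np.allclose(q, np.round(q), atol=1e-9):
            return size
    return minimum


def _new_block(state: AllocationState, rng: np.random.Generator) -> list:
    arms = np.flatnonzero(state.probs > _EPS)
    p = state.probs[arms]
    minimum = state.block_min if state.block_min is not None else 2 * len(arms)
    size = _block_size(p, minimum)
    quota = p * size
    base = np.floor(quota + 1e-9).astype(int)
    deficit = size - base.sum()
    if deficit > 0:
        # distribute leftover slots with probabilities proportional to the
        # fractional remainders, so block composition is unbiased
        rem = quota - base
        rem = np.where(rem < 0, 0.0, rem)
        extra = rng.choice(len(arms), size=deficit, replace=False, p=rem / rem.sum())
        base[extra] += 1
    block = np.repeat(arms, base)
    rng.shuffle(block)
    return block.tolist()


def assign_arm(
    state: AllocationState, stratum: Hashable, rng: Union[int, np.random.Generator]
) -> int:
    """Randomise one patient and return the assigned arm index.

    Block phase: pop from the stratum's permuted block, opening a new
    block when the buffer is empty (an unseen stratum simply gets a fresh
    block).  Simple phase: an independent draw from the probabilities in
    force.  Long-run frequencies converge to ``probs`` in both phases.
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if state.phase == "simple":
        return int(np.searchsorted(np.cumsum(state.probs), gen.random(), side="right"))
    buf = state.buffers.get(stratum)
    if not buf:
        buf = _new_block(state, gen)
        state.buffers[stratum] = buf
    return int(buf.pop())


def assign_batch(
    state: AllocationState,
    strata: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Randomise a batch of patients (vectorised in the simple phase)."""
    n = len(strata)
    if n == 0:
        return np.empty(0, dtype=int)
    if state.phase == "simple":
        cum = np.cumsum(state.probs)
        return np.searchsorted(cum, rng.random(n), side="right").astype(int)
    return np.array([assign_arm(state, s, rng) for s in strata], dtype=int)
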