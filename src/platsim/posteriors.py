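"""Conjugate Beta posteriors for the binary guiding outcome and the
Monte-Carlo probabilities consumed by the adaptation rules.

All decision probabilities — P(arm is overall best), P(better than the
common control by more than a margin), P(practical equivalence) — are
estimated from a single shared matrix of posterior draws per analysis
(common random numbers), so the decisions taken at one look are mutually
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "PosteriorSet",
    "ProbabilityReport",
    "update_beta",
    "prob_best",
    "prob_pairwise_better",
    "prob_all_equivalent",
]


def update_beta(
    prior_alpha: float, prior_beta: float, events: int, n: int
) -> tuple[float, float]:
    """Beta-binomial conjugate update: Beta(a, b) + (events, n) data.

    Returns (a + events, b + n - events).
    """
    if events < 0 or n < 0 or events > n:
        raise ValueError(f"need 0 <= events <= n, got events={events}, n={n}")
    return prior_alpha + events, prior_beta + (n - events)


@dataclass
class PosteriorSet:
    """Per-arm Beta posterior parameters for the guiding outcome.

    ``alpha``/``beta`` are vectors over the arms being analysed;
    ``direction`` says whether a higher or lower event probability is
    better (mortality-type guiding outcomes use ``lower_better``).
    """

    alpha: np.ndarray
    beta: np.ndarray
    direction: str = "lower_better"

    @classmethod
    def from_counts(
        cls,
        events: np.ndarray,
        totals: np.ndarray,
        prior_alpha: float = 1.0,
        prior_beta: float = 1.0,
        direction: str = "lower_better",
    ) -> "PosteriorSet":
        events = np.asarray(events, dtype=float)
        totals = np.asarray(totals, dtype=float)
        if np.any(events > totals) or np.any(events < 0):
            raise ValueError("need 0 <= events <= totals per arm")
        return cls(
            alpha=prior_alpha + events,
            beta=prior_beta + (totals - events),
            direction=direction,
        )

    def sample(self, n_draws: int, rng: Union[int, np.random.Generator]) -> np.ndarray:
        """Draw matrix of shape (n_draws, n_arms), each entry in (0, 1)."""
        gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        return gen.beta(self.alpha, self.beta, size=(n_draws, len(self.alpha)))


@dataclass
class ProbabilityReport:
    """Every posterior probability an adaptive analysis may consume.

    Entries are aligned with the active-arm draw matrix.  ``p_best`` sums
    to 1 exactly; fields not required by the configured rules are None.
    The reference/control entry of pairwise vectors is NaN.
    """

    p_best: np.ndarray
    p_better_than_control: Optional[np.ndarray] = None
    p_futility_superior: Optional[np.ndarray] = None
    p_all_equivalent: Optional[Union[float, np.ndarray]] = None
    n_draws: int = 0

    def to_json_dict(self) -> dict:
        def conv(x):
            if x is None:
                return None
            if isinstance(x, np.ndarray):
                return [None if np.isnan(v) else float(v) for v in x]
            return float(x)

        return {
            "p_best": conv(self.p_best),
            "p_better_than_control": conv(self.p_better_than_control),
            "p_futility_superior": conv(self.p_futility_superior),
            "p_all_equivalent": conv(self.p_all_equivalent),
            "n_draws": int(self.n_draws),
        }


def _check_draws(draws: np.ndarray) -> np.ndarray:
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 1 or draws.shape[1] < 2:
        raise ValueError("draws must be a (n_draws >= 1, n_arms >= 2) matrix")
    return draws


def prob_best(draws: np.ndarray, direction: str = "lower_better") -> np.ndarray:
    """Per-arm posterior probability of being overall best.

    The best arm in a draw attains the minimum event probability under
    ``lower_better`` (maximum under ``higher_better``).  Draws in which
    several arms tie split their mass equally among the tied arms, so the
    output sums to 1 exactly.
    """
    draws = _check_draws(draws)
    ext = draws.min(axis=1) if direction == "lower_better" else draws.max(axis=1)
    mask = draws == ext[:, None]
    counts = mask.sum(axis=1)
    return (mask / counts[:, None]).mean(axis=0)


def prob_pairwise_better(
    draws: np.ndarray,
    reference: int,
    margin: float = 0.0,
    direction: str = "lower_better",
) -> np.ndarray:
    """Per-arm probability of being better than ``reference`` by more than
    ``margin`` (an absolute risk difference >= 0).

    Under ``lower_better`` this is P(p_ref - p_arm > margin); under
    ``higher_better`` P(p_arm - p_ref > margin).  The reference entry is
    NaN.
    """
    draws = _check_draws(draws)
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if not (0 <= reference < draws.shape[1]):
        raise ValueError(f"reference index {reference} out of range")
    ref = draws[:, [reference]]
    diff = ref - draws if direction == "lower_better" else draws - ref
    out = (diff > margin).mean(axis=0)
    out[reference] = np.nan
    return out


def prob_all_equivalent(
    draws: np.ndarray,
    margin: float,
    mode: str = "all_vs_all",
    control: Optional[int] = None,
) -> Union[float, np.ndarray]:
    """Probability of practical equivalence.

    ``all_vs_all``: the fraction of draws in which the largest pairwise
    absolute difference across all arms is below ``margin`` (joint, per
    draw).  ``vs_control``: per-arm fraction of draws with
    \\|p_arm - p_control\\| < margin; the control entry is NaN.
    """
    draws = _check_draws(draws)
    if margin <= 0:
        raise ValueError("equivalence margin must be > 0")
    if mode == "all_vs_all":
        span = draws.max(axis=1) - draws.min(axis=1)
        return float((span < margin).mean())
    if mode == "vs_control":
        if control is None:
            raise ValueError("vs_control mode requires a control index")
        out = (np.abs(draws - draws[:, [control]]) < margin).mean(axis=0)
        out[control] = np.nan
        return out
    raise ValueError(f"unknown mode {mode!r}")
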