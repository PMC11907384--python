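"""Independent oracles for the posterior-probability operations.

These deliberately avoid the implementation's code paths: brute-force
estimates use scipy's beta sampler on the legacy Mersenne-Twister
generator, and the pairwise probability uses 1-D grid quadrature of the
product density.
"""

import numpy as np
from scipy import stats


def brute_force_p_best(alphas, betas, direction, n=1_000_000, seed=0):
    """Large-sample estimate of P(arm is best) via independent sampling."""
    rs = np.random.RandomState(seed)
    draws = np.column_stack(
        [stats.beta.rvs(a, b, size=n, random_state=rs) for a, b in zip(alphas, betas)]
    )
    idx = np.argmin(draws, axis=1) if direction == "lower_better" else np.argmax(draws, axis=1)
    return np.bincount(idx, minlength=len(alphas)) / n


def quadrature_p_better(a_arm, b_arm, a_ref, b_ref, margin, direction, step=1e-3):
    """P(arm better than reference by more than margin) by grid quadrature.

    lower_better: P(p_ref - p_arm > m) = int f_ref(x) F_arm(x - m) dx;
    higher_better: P(p_arm - p_ref > m) = int f_ref(x) (1 - F_arm(x + m)) dx.
    """
    x = np.arange(step / 2, 1.0, step)  # midpoint rule
    f_ref = stats.beta.pdf(x, a_ref, b_ref)
    if direction == "lower_better":
        inner = stats.beta.cdf(x - margin, a_arm, b_arm)
    else:
        inner = stats.beta.sf(x + margin, a_arm, b_arm)
    return float(np.sum(f_ref * inner) * step)


def brute_force_all_equivalent(alphas, betas, margin, n=1_000_000, seed=0):
    """Large-sample estimate of P(max pairwise difference < margin)."""
    rs = np.random.RandomState(seed)
    draws = np.column_stack(
        [stats.beta.rvs(a, b, size=n, random_state=rs) for a, b in zip(alphas, betas)]
    )
    span = draws.max(axis=1) - draws.min(axis=1)
    return float((span < margin).mean())


def mc_tolerance(p, *ns, floor=1e-3):
    """3 combined Monte-Carlo standard errors for comparing estimates."""
    p = min(max(p, 1e-6), 1 - 1e-6)
    var = sum(p * (1 - p) / n for n in ns)
    return 3 * np.sqrt(var) + floor
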