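"""Shared Monte Carlo machinery for the power and expected-posterior modules.

One replicate of the design simulation:

1. draw true failure probabilities pi1, pi0 from the *design* priors;
2. draw trial data r1 ~ Bin(n, pi1), r0 ~ Bin(n, pi0);
3. conjugately update the *analysis* priors and form the normal
   approximation to the risk-difference posterior;
4. draw the margin delta* (after the data draws, so a fixed margin and a
   degenerate uniform margin give identical streams for the same seed).

Grid searches reuse one seed across all candidate n (common random
numbers): the pi and margin draws are then identical at every grid
point, which removes most between-point Monte Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Tuple

import numpy as np

from .distributions import TrialScenario, sample_margin
from .errors import SearchNotFoundError

DEFAULT_REPS = 100_000
DEFAULT_STEP = 10
DEFAULT_N_MIN = 10
DEFAULT_N_MAX = 2000
ESCALATION_FACTOR = 10


@dataclass(frozen=True)
class Replicates:
    """Vectorised replicate draws for one (scenario, n, seed) triple."""

    pi1: np.ndarray        # true experimental failure probabilities
    pi0: np.ndarray        # true control failure probabilities
    delta_star: np.ndarray  # margin per replicate (constant when fixed)
    post_mean: np.ndarray  # posterior mean of pi1 - pi0
    post_sd: np.ndarray    # posterior SD of pi1 - pi0


def _posterior_moments(alpha: np.ndarray, beta: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    s = alpha + beta
    mean = alpha / s
    var = alpha * beta / (s * s * (s + 1.0))
    return mean, var


def draw_replicates(
    scenario: TrialScenario, n_per_group: int, reps: int, seed: Optional[int]
) -> Replicates:
    """Simulate ``reps`` trials of ``n_per_group`` per arm.

    With ``n_per_group == 0`` the data step is skipped and the posterior
    is the analysis prior itself.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n_per_group < 0:
        raise ValueError("n_per_group must be >= 0")
    rng = np.random.default_rng(seed)
    d1, d0 = scenario.experimental.design, scenario.control.design
    a1, a0 = scenario.experimental.analysis, scenario.control.analysis

    pi1 = rng.beta(d1.alpha, d1.beta, size=reps)
    pi0 = rng.beta(d0.alpha, d0.beta, size=reps)
    if n_per_group > 0:
        r1 = rng.binomial(n_per_group, pi1)
        r0 = rng.binomial(n_per_group, pi0)
    else:
        r1 = np.zeros(reps)
        r0 = np.zeros(reps)
    delta_star = sample_margin(scenario.margin, rng, size=reps)

    m1, v1 = _posterior_moments(a1.alpha + r1, a1.beta + n_per_group - r1)
    m0, v0 = _posterior_moments(a0.alpha + r0, a0.beta + n_per_group - r0)
    return Replicates(
        pi1=pi1,
        pi0=pi0,
        delta_star=delta_star,
        post_mean=m1 - m0,
        post_sd=np.sqrt(v1 + v0),
    )


def grid_search(
    estimate: Callable[[int, int], Tuple[float, float]],
    target: float,
    grid: Iterable[int],
    reps: int,
    what: str,
) -> int:
    """Smallest grid n whose estimate meets ``target``.

    ``estimate(n, reps)`` returns ``(value, mc_se)`` and must use common
    random numbers across calls.  When the first grid point meeting the
    target is within one Monte Carlo standard error of it, the two
    bracketing points are re-estimated once at ``ESCALATION_FACTOR``
    times the replicates before the decision is final; this stabilises
    searches whose answer sits right at the target.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty search grid")
    best_n, best_v = grid[0], -np.inf
    prev_n: Optional[int] = None
    i = 0
    while i < len(grid):
        n = grid[i]
        value, se = estimate(n, reps)
        if value > best_v:
            best_n, best_v = n, value
        if value >= target:
            if abs(value - target) < se:
                big = reps * ESCALATION_FACTOR
                if prev_n is not None:
                    v_prev, _ = estimate(prev_n, big)
                    if v_prev >= target:
                        return prev_n
                v_big, _ = estimate(n, big)
                if v_big >= target:
                    return n
                if v_big > best_v:
                    best_n, best_v = n, v_big
                # escalated estimate fell below target: keep scanning
            else:
                return n
        prev_n = n
        i += 1
    raise SearchNotFoundError(
        f"no grid point reached {what} >= {target}; "
        f"best was {best_v:.4f} at n = {best_n}",
        best_n=best_n,
        best_value=best_v,
    )
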