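"""Bayesian predictive power (assurance) for non-inferiority designs.

Predictive power is the joint probability, averaged over the design
priors, that the planned Bayesian analysis will declare non-inferiority
*and* that the declaration is correct:

    P(R) = E_{pi1, pi0} E_{r1, r0} [ I_S(r1, r0, n, delta*) I_NI(pi1, pi0) ],

where I_S indicates a "significant" Bayesian result — posterior
probability of ``delta < delta*`` exceeding ``1 - alpha/2``, evaluated
with the normal approximation to the risk-difference posterior — and
I_NI indicates that the true rates satisfy ``pi1 - pi0 < delta*``.
Restricting to the joint event excludes rejections that would be type I
errors; with a design prior supportive of non-inferiority the joint and
unconditional probabilities are nearly equal, and both are reported.

When the margin carries a prior, each replicate draws its own delta*
and uses it in both indicators, so the estimate is the expected
proportion of experts convinced by the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from . import _engine
from .distributions import TrialScenario

__all__ = ["PowerResult", "predictive_power", "find_n_for_power", "power_curve"]


@dataclass(frozen=True)
class PowerResult:
    """Monte Carlo predictive-power estimate with provenance.

    ``joint_power`` is the headline quantity (significant and correct);
    ``unconditional_power`` drops the correctness requirement;
    ``prob_sig_and_inferior`` is their difference — significant results
    that would be type I errors.  The three satisfy
    ``joint + sig_and_inferior = unconditional`` on every run.
    """

    joint_power: float
    unconditional_power: float
    prob_sig_and_inferior: float
    mc_se: float
    reps: int
    seed: Optional[int]
    n_per_group: int


def predictive_power(
    scenario: TrialScenario,
    n_per_group: int,
    reps: int = _engine.DEFAULT_REPS,
    seed: Optional[int] = None,
) -> PowerResult:
    """Estimate predictive power at a fixed per-group sample size."""
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    rep = _engine.draw_replicates(scenario, n_per_group, reps, seed)
    z = scenario.z_crit
    sig = (rep.delta_star - rep.post_mean) / rep.post_sd > z
    ni = rep.pi1 - rep.pi0 < rep.delta_star

    n_sig = int(sig.sum())
    n_joint = int((sig & ni).sum())
    joint = n_joint / reps
    return PowerResult(
        joint_power=joint,
        unconditional_power=n_sig / reps,
        prob_sig_and_inferior=(n_sig - n_joint) / reps,
        mc_se=math.sqrt(joint * (1.0 - joint) / reps),
        reps=reps,
        seed=seed,
        n_per_group=n_per_group,
    )


def find_n_for_power(
    scenario: TrialScenario,
    target: float,
    step: int = _engine.DEFAULT_STEP,
    n_min: int = _engine.DEFAULT_N_MIN,
    n_max: int = _engine.DEFAULT_N_MAX,
    reps: int = _engine.DEFAULT_REPS,
    seed: Optional[int] = None,
) -> int:
    """Smallest per-group n on the grid with predictive power >= target.

    The same seed is reused at every grid point (common random numbers),
    and estimates landing within one Monte Carlo standard error of the
    target trigger a tenfold replicate escalation at the two bracketing
    grid points before the decision is final.

    Raises
    ------
    SearchNotFoundError
        If no grid point reaches the target; carries the best (n, value).
    """
    if not (0.0 < target < 1.0):
        raise ValueError(f"target must lie in (0, 1), got {target}")
    if step < 1 or n_min < 1 or n_min > n_max:
        raise ValueError("need step >= 1 and 1 <= n_min <= n_max")

    def estimate(n: int, r: int):
        res = predictive_power(scenario, n, r, seed)
        return res.joint_power, res.mc_se

    return _engine.grid_search(
        estimate, target, range(n_min, n_max + 1, step), reps, what="predictive power"
    )


def power_curve(
    scenario: TrialScenario,
    n_values: Iterable[int],
    reps: int = _engine.DEFAULT_REPS,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Predictive power tabulated over sample sizes (common random numbers).

    Returns a DataFrame with one row per n, ordered by n, with columns
    ``n, joint_power, unconditional_power, prob_sig_and_inferior, mc_se,
    reps, seed``.
    """
    n_values = sorted(set(int(n) for n in n_values))
    if not n_values:
        raise ValueError("n_values must be non-empty")
    rows = []
    for n in n_values:
        res = predictive_power(scenario, n, reps, seed)
        rows.append(
            {
                "n": n,
                "joint_power": res.joint_power,
                "unconditional_power": res.unconditional_power,
                "prob_sig_and_inferior": res.prob_sig_and_inferior,
                "mc_se": res.mc_se,
                "reps": res.reps,
                "seed": res.seed,
            }
        )
    return pd.DataFrame(rows)
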