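"""Expected posterior probability of non-inferiority.

Instead of asking how often the trial will produce a *significant*
result, this approach controls the expectation, over the predictive
distribution of the data, of the posterior probability that the risk
difference is below the margin:

    e_n = E_{p_n} [ P(delta < delta* | data) ].

The minimum n giving an acceptable e_n is typically smaller than the
predictive-power answer, because only the mean of the posterior-
probability distribution is controlled, not its spread.  At n = 0 no
data are drawn and e_0 is simply the analysis prior's probability of
non-inferiority — a scenario whose analysis prior already carries 90%+
support needs no patients at all by this criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from .distributions import TrialScenario, diff_posterior_normal, prob_diff_below

__all__ = ["EppResult", "expected_posterior_prob", "find_n_for_epp", "epp_curve"]


@dataclass(frozen=True)
class EppResult:
    """Expected posterior probability of non-inferiority at one n."""

    e_n: float
    mc_se: float
    reps: int
    seed: Optional[int]
    n_per_group: int


def expected_posterior_prob(
    scenario: TrialScenario,
    n_per_group: int,
    reps: int = _engine.DEFAULT_REPS,
    seed: Optional[int] = None,
) -> EppResult:
    """Estimate e_n by simulation from the design priors.

    For ``n_per_group == 0`` with a fixed margin the value is exact (the
    analysis-prior probability of non-inferiority) and ``mc_se`` is 0;
    with a margin prior the margin draw is still simulated.
    """
    if n_per_group < 0:
        raise ValueError(f"n_per_group must be >= 0, got {n_per_group}")
    if n_per_group == 0 and scenario.margin.kind == "fixed":
        summary = diff_posterior_normal(
            scenario.experimental.analysis, scenario.control.analysis
        )
        value = prob_diff_below(summary, scenario.margin.value)
        return EppResult(e_n=value, mc_se=0.0, reps=reps, seed=seed, n_per_group=0)

    rep = _engine.draw_replicates(scenario, n_per_group, reps, seed)
    post_prob = stats.norm.cdf((rep.delta_star - rep.post_mean) / rep.post_sd)
    e_n = float(np.mean(post_prob))
    se = float(np.std(post_prob, ddof=1)) / math.sqrt(reps) if reps > 1 else 0.0
    return EppResult(e_n=e_n, mc_se=se, reps=reps, seed=seed, n_per_group=n_per_group)


def find_n_for_epp(
    scenario: TrialScenario,
    target: float,
    step: int = _engine.DEFAULT_STEP,
    n_min: int = 0,
    n_max: int = _engine.DEFAULT_N_MAX,
    reps: int = _engine.DEFAULT_REPS,
    seed: Optional[int] = None,
) -> int:
    """Smallest per-group n on the grid with e_n >= target.

    ``n_min`` may be 0: when the analysis prior alone already meets the
    target the search returns 0 and no patients are needed.  Shares the
    common-random-numbers and boundary-escalation conventions of the
    power search.
    """
    if not (0.0 < target < 1.0):
        raise ValueError(f"target must lie in (0, 1), got {target}")
    if step < 1 or n_min < 0 or n_min > n_max:
        raise ValueError("need step >= 1 and 0 <= n_min <= n_max")

    def estimate(n: int, r: int):
        res = expected_posterior_prob(scenario, n, r, seed)
        return res.e_n, res.mc_se

    return _engine.grid_search(
        estimate,
        target,
        range(n_min, n_max + 1, step),
        reps,
        what="expected posterior probability",
    )


def epp_curve(
    scenario: TrialScenario,
    n_values: Iterable[int],
    reps: int = _engine.DEFAULT_REPS,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """e_n tabulated over sample sizes (common random numbers); columns
    ``n, e_n, mc_se, reps, seed``."""
    n_values = sorted(set(int(n) for n in n_values))
    if not n_values:
        raise ValueError("n_values must be non-empty")
    rows = []
    for n in n_values:
        res = expected_posterior_prob(scenario, n, reps, seed)
        rows.append(
            {"n": n, "e_n": res.e_n, "mc_se": res.mc_se, "reps": res.reps, "seed": res.seed}
        )
    return pd.DataFrame(rows)
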