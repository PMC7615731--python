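"""Precision-based sample size: credible-interval width and ACCEPT curves.

This approach asks what precision a given per-group sample size buys for
the risk-difference posterior, regardless of any non-inferiority margin.
With conjugate Beta analysis priors and assumed observed failure
proportions p1, p0, the posterior of each arm at sample size n is
Beta(a + n p, b + n (1 - p)) (fractional pseudo-counts are fine), the
risk-difference posterior is approximated as normal, and the
100(1-alpha)% interval width is the closed form

    width(n) = 2 Z_{alpha/2} sqrt( V1(n) + V0(n) ),

with V the exact Beta posterior variances.  Everything here is
deterministic — design priors play no role and no simulation is needed.

ACCEPT (ACceptability Curve Estimation using Probability above
Threshold) plots the posterior exceedance probability
P(delta > threshold | data) against a range of thresholds; steeper
curves mean more informative sample sizes, and the curve passes through
0.5 exactly at the posterior mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import BetaParams, NormalSummary
from .errors import SearchNotFoundError

__all__ = [
    "PrecisionInputs",
    "AcceptCurve",
    "ci_width",
    "width_curve",
    "n_for_width",
    "accept_prob",
    "accept_curve",
]


@dataclass(frozen=True)
class PrecisionInputs:
    """Analysis priors plus assumed observed failure proportions.

    ``p1_assumed`` / ``p0_assumed`` must be given explicitly: common
    practice sets them to the analysis-prior means for informative
    priors, but to the anticipated event rates (not 50%) when the
    analysis priors are flat Beta(1,1).
    """

    analysis_experimental: BetaParams
    analysis_control: BetaParams
    p1_assumed: float
    p0_assumed: float
    level: float = 0.95

    def __post_init__(self) -> None:
        for name in ("p1_assumed", "p0_assumed", "level"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class AcceptCurve:
    """P(delta > threshold | data) over an ascending threshold grid."""

    n_per_group: int
    thresholds: Tuple[float, ...]
    probabilities: Tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds)
        p = np.asarray(self.probabilities)
        if t.size != p.size or t.size == 0:
            raise ValueError("thresholds and probabilities must be non-empty and equal length")
        if np.any(np.diff(t) < 0):
            raise ValueError("thresholds must be ascending")
        if np.any((p < 0) | (p > 1)) or np.any(np.diff(p) > 1e-12):
            raise ValueError("probabilities must be in [0,1] and non-increasing")

    def as_frame(self) -> pd.DataFrame:
        """Long-format (threshold, probability, n) table for re-plotting."""
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "probability": self.probabilities,
                "n": self.n_per_group,
            }
        )


def _posterior_summary(inputs: PrecisionInputs, n_per_group: float) -> NormalSummary:
    """Normal summary of the risk-difference posterior at assumed counts n*p."""
    if n_per_group < 0:
        raise ValueError(f"n_per_group must be >= 0, got {n_per_group}")

    def moments(prior: BetaParams, p: float):
        a = prior.alpha + n_per_group * p
        b = prior.beta + n_per_group * (1.0 - p)
        s = a + b
        return a / s, a * b / (s * s * (s + 1.0))

    m1, v1 = moments(inputs.analysis_experimental, inputs.p1_assumed)
    m0, v0 = moments(inputs.analysis_control, inputs.p0_assumed)
    return NormalSummary(mean=m1 - m0, variance=v1 + v0)


def ci_width(inputs: PrecisionInputs, n_per_group: int) -> float:
    """Width of the equal-tailed credible interval for the risk difference.

    Strictly decreasing in n and tending to 0; at n = 0 it reflects the
    analysis priors alone.
    """
    summary = _posterior_summary(inputs, n_per_group)
    z = stats.norm.ppf(1.0 - (1.0 - inputs.level) / 2.0)
    return float(2.0 * z * summary.sd)


def width_curve(inputs: PrecisionInputs, n_grid: Iterable[int]) -> pd.DataFrame:
    """(n, width) table over an ascending grid of per-group sizes."""
    ns = sorted(set(int(n) for n in n_grid))
    if not ns:
        raise ValueError("n_grid must be non-empty")
    return pd.DataFrame({"n": ns, "width": [ci_width(inputs, n) for n in ns]})


def n_for_width(
    inputs: PrecisionInputs,
    target_width: float,
    step: int = 10,
    n_max: int = 10_000,
    n_min: int = 0,
) -> int:
    """Smallest grid n whose interval width is <= target_width (deterministic).

    Raises
    ------
    SearchNotFoundError
        If even ``n_max`` leaves the interval wider than the target.
    """
    if target_width <= 0.0:
        raise ValueError(f"target_width must be positive, got {target_width}")
    if step < 1 or n_min < 0 or n_min > n_max:
        raise ValueError("need step >= 1 and 0 <= n_min <= n_max")
    best_n, best_w = n_min, math.inf
    for n in range(n_min, n_max + 1, step):
        w = ci_width(inputs, n)
        if w < best_w:
            best_n, best_w = n, w
        if w <= target_width:
            return n
    raise SearchNotFoundError(
        f"interval width {best_w:.4f} at n = {best_n} still exceeds "
        f"target {target_width}",
        best_n=best_n,
        best_value=best_w,
    )


def accept_prob(inputs: PrecisionInputs, n_per_group: int, threshold: float) -> float:
    """Posterior probability that the risk difference exceeds ``threshold``.

    1 - Phi((threshold - mu) / sigma) with mu, sigma from the Beta
    posterior moments at assumed counts; exactly 0.5 at the posterior
    mean.
    """
    summary = _posterior_summary(inputs, n_per_group)
    return float(1.0 - stats.norm.cdf((threshold - summary.mean) / summary.sd))


def accept_curve(
    inputs: PrecisionInputs, n_per_group: int, thresholds: Sequence[float]
) -> AcceptCurve:
    """ACCEPT curve at one sample size over ascending thresholds."""
    t = [float(x) for x in thresholds]
    probs: List[float] = [accept_prob(inputs, n_per_group, x) for x in t]
    return AcceptCurve(
        n_per_group=n_per_group, thresholds=tuple(t), probabilities=tuple(probs)
    )
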