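"""Standard frequentist sample size for non-inferiority with binary outcomes.

The per-group sample size solves

    n = (Z_{alpha/2} + Z_beta)^2 / f,
    f = (pi_e1 - pi_e0 - delta*)^2 / [pi_e1 (1 - pi_e1) + pi_e0 (1 - pi_e0)],

where ``pi_e1`` and ``pi_e0`` are the expected failure proportions
assumed fixed and known, ``delta*`` the non-inferiority margin, and
``Z_q`` upper standard-normal quantiles.  Equal allocation is assumed.
The result is rounded to the *nearest* integer (half away from zero),
which reproduces the conventional printed values, e.g. margins
{5, 7.5, 10, 12.5, 15}% at 18% failure in both arms give per-group sizes
{1241, 551, 310, 199, 138}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import InfeasibleDesignError

__all__ = [
    "FrequentistInputs",
    "required_n",
    "power_given_n",
    "adjust_for_attrition",
]


@dataclass(frozen=True)
class FrequentistInputs:
    """Inputs to the frequentist non-inferiority sample-size formula."""

    p1_expected: float
    p0_expected: float
    margin: float
    alpha: float = 0.05
    power: float = 0.90

    def __post_init__(self) -> None:
        for name in ("p1_expected", "p0_expected", "margin", "alpha", "power"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def _effect_f(p1: float, p0: float, margin: float) -> float:
    """The effect-size term f; positive only for a feasible design."""
    num = p1 - p0 - margin
    if num >= 0.0:
        raise InfeasibleDesignError(
            f"margin {margin} must exceed the expected risk difference "
            f"{p1 - p0:+.4g}; no finite sample size can show non-inferiority"
        )
    denom = p1 * (1.0 - p1) + p0 * (1.0 - p0)
    return num * num / denom


def required_n(inputs: FrequentistInputs) -> int:
    """Per-group sample size for the requested power, nearest-integer rounded."""
    z_a = stats.norm.ppf(1.0 - inputs.alpha / 2.0)
    z_b = stats.norm.ppf(inputs.power)
    f = _effect_f(inputs.p1_expected, inputs.p0_expected, inputs.margin)
    n = (z_a + z_b) ** 2 / f
    return max(1, math.floor(n + 0.5))


def power_given_n(
    p1_expected: float,
    p0_expected: float,
    margin: float,
    alpha: float,
    n: int,
) -> float:
    """Frequentist power at a given per-group n (inverse of required_n).

    Returns Phi(sqrt(n f) - Z_{alpha/2}); monotone increasing in n.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    f = _effect_f(p1_expected, p0_expected, margin)
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(math.sqrt(n * f) - z_a))


def adjust_for_attrition(n_per_group: int, loss_fraction: float) -> int:
    """Inflate a per-group size for anticipated loss to follow-up.

    Returns ceiling(n / (1 - loss)); e.g. 310 per group at 10% loss
    becomes 345.
    """
    if not (0.0 <= loss_fraction < 1.0):
        raise ValueError(f"loss_fraction must lie in [0, 1), got {loss_fraction}")
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    return math.ceil(n_per_group / (1.0 - loss_fraction))
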