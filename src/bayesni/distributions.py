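"""Beta-distribution machinery for two-arm binary-outcome trial design.

The package models each trial arm's failure probability with a conjugate
Beta distribution.  Two distinct roles are supported per arm: a *design*
prior, encoding planning-stage uncertainty about the true failure
proportion, and an *analysis* prior, the one the eventual Bayesian
analysis will actually use.  The treatment effect is the risk difference
``delta = pi1 - pi0`` (experimental minus control, outcome = failure, so
higher is worse), and non-inferiority means ``delta < delta*`` for a
positive margin ``delta*``.

The posterior of the risk difference is approximated by a normal
distribution whose mean and variance come from the exact Beta posterior
moments of the two arms; this approximation is the default computational
path throughout the package, with exact-Beta Monte Carlo available as a
verification method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy import stats

from .errors import InvalidMomentsError

__all__ = [
    "BetaParams",
    "ArmPriorPair",
    "MarginSpec",
    "NormalSummary",
    "TrialScenario",
    "MonteCarloEstimate",
    "beta_from_moments",
    "beta_moments",
    "effective_sample_size",
    "central_interval",
    "posterior_update",
    "diff_posterior_normal",
    "prob_diff_below",
    "prior_prob_ni",
    "sample_margin",
]


@dataclass(frozen=True)
class BetaParams:
    """A Beta(alpha, beta) distribution for one arm's failure probability.

    ``alpha`` acts as a pseudo-count of events (failures) and ``beta`` as
    a pseudo-count of non-events; ``alpha + beta`` is the prior's
    effective sample size.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"Beta parameters must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class ArmPriorPair:
    """Design and analysis priors for a single trial arm.

    The two priors need not coincide: external information may be
    acceptable for planning (design) while the analysis stays vague, or
    vice versa.
    """

    design: BetaParams
    analysis: BetaParams


@dataclass(frozen=True)
class MarginSpec:
    """A non-inferiority margin: a fixed value or a Uniform prior.

    A prior on the margin represents variability of opinion among
    experts about the largest clinically acceptable excess failure risk;
    the expected operating characteristic is then an expected proportion
    of experts convinced by the analysis.
    """

    kind: str  # "fixed" | "uniform"
    value: Optional[float] = None
    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "fixed":
            if self.value is None or not (0.0 < self.value < 1.0):
                raise ValueError(
                    f"fixed margin must lie strictly in (0, 1), got {self.value}"
                )
        elif self.kind == "uniform":
            if (
                self.lower is None
                or self.upper is None
                or not (0.0 < self.lower < self.upper < 1.0)
            ):
                raise ValueError(
                    "uniform margin bounds must satisfy 0 < lower < upper < 1, "
                    f"got ({self.lower}, {self.upper})"
                )
        else:
            raise ValueError(f"margin kind must be 'fixed' or 'uniform', got {self.kind!r}")

    @classmethod
    def fixed(cls, value: float) -> "MarginSpec":
        return cls(kind="fixed", value=value)

    @classmethod
    def uniform(cls, lower: float, upper: float) -> "MarginSpec":
        return cls(kind="uniform", lower=lower, upper=upper)

    @property
    def midpoint(self) -> float:
        """Central margin value (the fixed value, or the uniform mean)."""
        if self.kind == "fixed":
            return float(self.value)
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class NormalSummary:
    """Mean and variance of the normal approximation to the risk-difference
    posterior."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"variance must be positive, got {self.variance}")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class TrialScenario:
    """Full specification of a two-arm non-inferiority design problem.

    Parameters
    ----------
    experimental, control
        Design/analysis prior pairs for each arm's failure probability.
    margin
        The non-inferiority margin, fixed or with a Uniform prior.
    alpha
        Two-sided significance level; a "significant" Bayesian result is
        a posterior probability of non-inferiority exceeding 1 - alpha/2.
    """

    experimental: ArmPriorPair
    control: ArmPriorPair
    margin: MarginSpec
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")

    @property
    def z_crit(self) -> float:
        """Upper alpha/2 standard-normal quantile."""
        return float(stats.norm.ppf(1.0 - self.alpha / 2.0))


@dataclass(frozen=True)
class MonteCarloEstimate:
    """A simulated probability with its Monte Carlo provenance."""

    value: float
    mc_se: float
    reps: int
    seed: Optional[int]


def beta_from_moments(mean: float, sd: float, round_params: bool = False) -> BetaParams:
    """Moment-match a Beta distribution to a given mean and SD.

    Solves ``alpha = mean * K``, ``beta = (1 - mean) * K`` with
    ``K = mean (1 - mean) / sd^2 - 1``.  With ``round_params`` each
    parameter is independently rounded to the nearest integer, which is
    how informative priors are conventionally reported (e.g. mean 18%,
    SD 2% gives Beta(66, 302)).

    Raises
    ------
    InvalidMomentsError
        If ``sd^2 >= mean (1 - mean)``: no Beta distribution has that
        much spread at that mean.
    """
    if not (0.0 < mean < 1.0):
        raise InvalidMomentsError(f"mean must lie in (0, 1), got {mean}")
    if sd <= 0.0:
        raise InvalidMomentsError(f"sd must be positive, got {sd}")
    m1m = mean * (1.0 - mean)
    if sd * sd >= m1m:
        raise InvalidMomentsError(
            f"no Beta distribution has mean {mean} and sd {sd} "
            f"(requires sd^2 < {m1m:.6g})"
        )
    k = m1m / (sd * sd) - 1.0
    a = mean * k
    b = (1.0 - mean) * k
    if round_params:
        a = round(a)
        b = round(b)
        if a < 1 or b < 1:
            raise InvalidMomentsError(
                f"rounded parameters ({a}, {b}) are not both positive; "
                "use round_params=False"
            )
    return BetaParams(a, b)


def beta_moments(p: BetaParams) -> Tuple[float, float]:
    """Return (mean, sd) of a Beta distribution; inverse of moment matching."""
    return p.mean, p.sd


def effective_sample_size(p: BetaParams) -> float:
    """Number of observations the prior is worth: alpha + beta."""
    return p.alpha + p.beta


def central_interval(p: BetaParams, level: float = 0.95) -> Tuple[float, float]:
    """Equal-tailed credible interval from exact Beta quantiles."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    lo, hi = stats.beta.ppf([tail, 1.0 - tail], p.alpha, p.beta)
    return float(lo), float(hi)


def posterior_update(p: BetaParams, events: int, size: int) -> BetaParams:
    """Conjugate update: Beta(a, b) with r events in n trials -> Beta(a+r, b+n-r)."""
    if events < 0 or size < 0 or events > size:
        raise ValueError(
            f"need 0 <= events <= size, got events={events}, size={size}"
        )
    return BetaParams(p.alpha + events, p.beta + size - events)


def diff_posterior_normal(experimental: BetaParams, control: BetaParams) -> NormalSummary:
    """Normal approximation to the distribution of ``delta = pi1 - pi0``.

    The mean is the difference of the exact Beta means and the variance
    the sum of the exact Beta variances (the arms are independent).
    """
    return NormalSummary(
        mean=experimental.mean - control.mean,
        variance=experimental.variance + control.variance,
    )


def prob_diff_below(summary: NormalSummary, threshold: float) -> float:
    """P(delta < threshold) under the normal approximation.

    The complement, P(delta > threshold), is the exceedance probability
    plotted on ACCEPT curves; the two always sum to one.
    """
    return float(stats.norm.cdf((threshold - summary.mean) / summary.sd))


def prior_prob_ni(
    experimental: BetaParams,
    control: BetaParams,
    margin: float,
    method: str = "normal",
    reps: int = 1_000_000,
    seed: Optional[int] = None,
) -> Union[float, MonteCarloEstimate]:
    """Probability of non-inferiority, P(pi1 - pi0 < margin), under two
    independent Beta distributions.

    ``method="normal"`` uses the normal approximation to the difference
    and returns a bare float; ``method="mc"`` samples the two Betas
    directly and returns a :class:`MonteCarloEstimate` (the exact-Beta
    verification route).
    """
    if not (0.0 < margin < 1.0):
        raise ValueError(f"margin must lie in (0, 1), got {margin}")
    if method == "normal":
        return prob_diff_below(diff_posterior_normal(experimental, control), margin)
    if method == "mc":
        if reps < 1:
            raise ValueError("reps must be >= 1")
        rng = np.random.default_rng(seed)
        pi1 = rng.beta(experimental.alpha, experimental.beta, size=reps)
        pi0 = rng.beta(control.alpha, control.beta, size=reps)
        p_hat = float(np.mean(pi1 - pi0 < margin))
        se = math.sqrt(p_hat * (1.0 - p_hat) / reps)
        return MonteCarloEstimate(value=p_hat, mc_se=se, reps=reps, seed=seed)
    raise ValueError(f"method must be 'normal' or 'mc', got {method!r}")


def sample_margin(
    margin: MarginSpec,
    rng: Optional[np.random.Generator] = None,
    size: Optional[int] = None,
):
    """Draw the non-inferiority margin: deterministic when fixed, a
    Uniform(lower, upper) draw otherwise.

    With ``size`` an array is returned (a fixed margin broadcasts to a
    constant array without consuming random state).
    """
    if margin.kind == "fixed":
        if size is None:
            return float(margin.value)
        return np.full(size, float(margin.value))
    if rng is None:
        raise ValueError("a random generator is required for a uniform margin")
    draw = rng.uniform(margin.lower, margin.upper, size=size)
    return float(draw) if size is None else draw
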