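"""Beta machinery: moment matching, conjugacy, normal approximation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bayesni as b
from bayesni.errors import InvalidMomentsError

# strategies for well-conditioned Beta parameters
betas = st.builds(
    b.BetaParams,
    st.floats(0.5, 500.0, allow_nan=False),
    st.floats(0.5, 500.0, allow_nan=False),
)


class TestMomentMatching:
    @pytest.mark.parametrize(
        "mean, sd, expected",
        [
            (0.18, 0.02, (66, 302)),
            (0.28, 0.02, (141, 362)),
        ],
    )
    def test_rounded_match_reproduces_reported_priors(self, mean, sd, expected):
        p = b.beta_from_moments(mean, sd, round_params=True)
        assert (p.alpha, p.beta) == expected

    def test_uniform_moments_round_trip_without_rounding(self):
        p = b.beta_from_moments(0.5, math.sqrt(1 / 12), round_params=False)
        assert p.alpha == pytest.approx(1.0)
        assert p.beta == pytest.approx(1.0)

    def test_infeasible_variance_raises(self):
        with pytest.raises(InvalidMomentsError):
            b.beta_from_moments(0.18, 0.5)
        with pytest.raises(InvalidMomentsError):
            b.beta_from_moments(0.5, 0.5)  # sd^2 == m(1-m) boundary

    @pytest.mark.parametrize(
        "params, mean, sd",
        [
            ((66, 302), 0.179, 0.020),
            ((1, 1), 0.5, math.sqrt(1 / 12)),
            ((11, 48), 0.186, 0.050),
        ],
    )
    def test_beta_moments(self, params, mean, sd):
        m, s = b.beta_moments(b.BetaParams(*params))
        assert m == pytest.approx(mean, abs=5e-4)
        assert s == pytest.approx(sd, abs=5e-4)

    @given(betas)
    def test_moment_round_trip(self, p):
        m, s = b.beta_moments(p)
        q = b.beta_from_moments(m, s, round_params=False)
        assert q.alpha == pytest.approx(p.alpha, rel=1e-8)
        assert q.beta == pytest.approx(p.beta, rel=1e-8)


class TestConjugacy:
    @pytest.mark.parametrize(
        "prior, events, size, expected",
        [
            ((1, 1), 0, 0, (1, 1)),
            ((1, 1), 56, 310, (57, 255)),
            ((66, 302), 56, 310, (122, 556)),
        ],
    )
    def test_posterior_update(self, prior, events, size, expected):
        post = b.posterior_update(b.BetaParams(*prior), events, size)
        assert (post.alpha, post.beta) == expected

    @pytest.mark.parametrize("events, size", [(-1, 10), (11, 10), (1, -1)])
    def test_invalid_counts_raise(self, events, size):
        with pytest.raises(ValueError):
            b.posterior_update(b.BetaParams(1, 1), events, size)

    @given(betas, st.integers(0, 500), st.integers(0, 500))
    def test_ess_additivity(self, p, r, extra):
        n = r + extra  # guarantees r <= n
        post = b.posterior_update(p, r, n)
        assert b.effective_sample_size(post) == pytest.approx(
            b.effective_sample_size(p) + n, rel=1e-12
        )

    @pytest.mark.parametrize(
        "params, ess", [((66, 302), 368), ((1, 1), 2), ((141, 362), 503)]
    )
    def test_effective_sample_size(self, params, ess):
        assert b.effective_sample_size(b.BetaParams(*params)) == ess


class TestCentralInterval:
    def test_design_prior_95_range_rounds_to_14_22_percent(self):
        lo, hi = b.central_interval(b.BetaParams(66, 302), 0.95)
        assert round(lo, 2) == 0.14
        assert round(hi, 2) == 0.22

    def test_uniform_quantiles(self):
        lo, hi = b.central_interval(b.BetaParams(1, 1), 0.95)
        assert lo == pytest.approx(0.025)
        assert hi == pytest.approx(0.975)

    def test_exact_quantiles_match_monte_carlo(self):
        # independent oracle: empirical quantiles of 10^6 Beta(11,48) draws
        rng = np.random.default_rng(2024)
        draws = rng.beta(11, 48, size=1_000_000)
        mc_lo, mc_hi = np.quantile(draws, [0.025, 0.975])
        lo, hi = b.central_interval(b.BetaParams(11, 48), 0.95)
        assert lo == pytest.approx(mc_lo, abs=5e-4)
        assert hi == pytest.approx(mc_hi, abs=5e-4)

    @given(betas, st.floats(0.5, 0.99))
    def test_interval_brackets_mean_and_widens_with_level(self, p, level):
        lo, hi = b.central_interval(p, level)
        assert lo < p.mean < hi
        lo2, hi2 = b.central_interval(p, level + 0.009)
        assert lo2 <= lo and hi2 >= hi


class TestDiffPosteriorNormal:
    def test_symmetric_flat_pair(self):
        s = b.diff_posterior_normal(b.BetaParams(1, 1), b.BetaParams(1, 1))
        assert s.mean == pytest.approx(0.0)
        assert s.variance == pytest.approx(1 / 6)

    def test_enthusiastic_pair_closed_form(self):
        # 2 * (11*48) / (59^2 * 60)
        s = b.diff_posterior_normal(b.BetaParams(11, 48), b.BetaParams(11, 48))
        assert s.mean == pytest.approx(0.0)
        assert s.variance == pytest.approx(2 * 11 * 48 / (59**2 * 60), rel=1e-12)
        assert s.variance == pytest.approx(0.00506, abs=1e-5)

    def test_skeptical_pair_mean(self):
        s = b.diff_posterior_normal(b.BetaParams(141, 362), b.BetaParams(66, 302))
        assert s.mean == pytest.approx(141 / 503 - 66 / 368, rel=1e-12)
        assert s.mean == pytest.approx(0.101, abs=5e-4)


class TestProbDiffBelow:
    def test_symmetry_at_zero(self):
        assert b.prob_diff_below(b.NormalSummary(0.0, 0.2), 0.0) == pytest.approx(0.5)

    def test_flat_pair_margin_10_percent(self):
        # Phi(0.1 * sqrt(6))
        got = b.prob_diff_below(b.NormalSummary(0.0, 1 / 6), 0.1)
        assert got == pytest.approx(0.5967, abs=5e-4)

    def test_far_threshold_saturates(self):
        assert b.prob_diff_below(b.NormalSummary(0.0, 1e-4), 50.0) == pytest.approx(1.0)

    @given(betas, betas, st.floats(-0.5, 0.5))
    def test_complement_of_exceedance(self, p1, p0, t):
        # P(delta < t) from this module and the ACCEPT exceedance
        # P(delta > t) (evaluated at n=0, i.e. on the priors themselves)
        # must sum to one.
        below = b.prob_diff_below(b.diff_posterior_normal(p1, p0), t)
        inputs = b.PrecisionInputs(p1, p0, 0.5, 0.5)
        above = b.accept_prob(inputs, 0, t)
        assert below + above == pytest.approx(1.0, abs=1e-12)


class TestPriorProbNI:
    def test_enthusiastic_prior_supports_ni_at_92_percent(self):
        est = b.prior_prob_ni(
            b.BetaParams(11, 48), b.BetaParams(11, 48), 0.10, method="mc",
            reps=1_000_000, seed=11,
        )
        assert round(est.value, 2) == 0.92

    def test_exchangeable_pair_at_zero_margin(self):
        # margin 0 is outside the validated range; use symmetry of a tiny one
        lo = b.prior_prob_ni(b.BetaParams(30, 70), b.BetaParams(30, 70), 1e-9)
        assert lo == pytest.approx(0.5, abs=1e-6)

    def test_design_prior_pair_normal_closed_form(self):
        p = b.BetaParams(66, 302)
        sd = math.sqrt(2 * p.variance)
        from scipy.stats import norm

        expected = norm.cdf(0.10 / sd)
        got = b.prior_prob_ni(p, p, 0.10, method="normal")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.9998, abs=2e-4)

    @pytest.mark.parametrize(
        "pair",
        [(66, 302), (11, 48), (141, 362)],
        ids=["design", "enthusiastic", "skeptical-exp"],
    )
    def test_mc_converges_to_normal_approximation(self, pair):
        p = b.BetaParams(*pair)
        normal = b.prior_prob_ni(p, p, 0.10, method="normal")
        mc = b.prior_prob_ni(p, p, 0.10, method="mc", reps=400_000, seed=3)
        assert abs(mc.value - normal) < 3 * mc.mc_se + 0.005


class TestSampleMargin:
    def test_fixed_margin_is_deterministic(self):
        assert b.sample_margin(b.MarginSpec.fixed(0.10)) == 0.10

    def test_uniform_sample_moments(self):
        rng = np.random.default_rng(99)
        draws = b.sample_margin(b.MarginSpec.uniform(0.05, 0.15), rng, size=100_000)
        assert draws.mean() == pytest.approx(0.10, abs=2e-4)
        assert draws.var() == pytest.approx(0.10**2 / 12, rel=0.02)
        assert draws.min() >= 0.05 and draws.max() <= 0.15

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kind": "fixed", "value": 0.0},
            {"kind": "fixed", "value": 1.2},
            {"kind": "uniform", "lower": 0.12, "upper": 0.08},
            {"kind": "uniform", "lower": 0.0, "upper": 0.1},
            {"kind": "gamma"},
        ],
    )
    def test_invalid_margin_specs_raise(self, kwargs):
        with pytest.raises(ValueError):
            b.MarginSpec(**kwargs)
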