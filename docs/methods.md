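# Methods

## Model and conventions

Both arms of a two-arm trial have a binary unfavourable outcome
("failure"); π₁ and π₀ are the experimental- and control-arm failure
probabilities, the treatment effect is the risk difference δ = π₁ − π₀,
and non-inferiority means δ < δ* for a positive margin δ*. Higher is
worse throughout; these conventions are fixed package-wide.

Each arm's failure probability carries Beta priors in two roles:

- **Design prior** Beta(a_D, b_D): planning-stage uncertainty about the
  true rate. Used only to average operating characteristics
  (predictive power, expected posterior probability).
- **Analysis prior** Beta(a_A, b_A): what the trial's Bayesian
  analysis will use; vague or informative, and not necessarily equal
  to the design prior.

With r events in n patients the conjugate posterior is
Beta(a_A + r, b_A + n − r). The posterior of δ is approximated as
normal,

    δ | r₁, r₀ ~ N( E[π₁|r₁] − E[π₀|r₀],  Var[π₁|r₁] + Var[π₀|r₀] ),

with exact Beta moments. This normal approximation is the default
computational path everywhere (significance indicators, posterior
probabilities, interval widths); exact-Beta Monte Carlo sampling is
exposed only as a verification route (`prior_prob_ni(method="mc")` and
the oracle checks in the test suite). For the flat-prior, no-data case
the two differ by less than 0.002 (Φ(0.1√6) = 0.597 vs the exact 0.595).

A "significant Bayesian result" at two-sided level α is
P(δ < δ* | data) > 1 − α/2, i.e. (δ* − μ_post)/σ_post > Z_{α/2}.

## Predictive power

Per Monte Carlo replicate: draw π₁, π₀ from the design priors, δ* from
its margin specification, r₁ ~ Bin(n, π₁), r₀ ~ Bin(n, π₀); update the
analysis priors; evaluate the significance indicator I_S and the
truth indicator I_NI = 1{π₁ − π₀ < δ*}. The headline estimate is the
mean of I_S·I_NI — the joint probability of a significant result that
is also correct — with the unconditional mean of I_S and the
type-I-error mass (significant but inferior) reported alongside; the
three satisfy joint + wrong = unconditional on every run. When the
margin has a Uniform prior, each replicate's δ* enters both indicators,
so the estimate reads as the expected proportion of experts (whose
opinions the margin prior represents) convinced by the analysis.

Restricting to the joint event rather than unconditional significance
matters little when the design prior supports non-inferiority (the
bundled base scenario has prior NI probability 0.9998), and the
difference is bounded by the design-prior probability of inferiority.

## Expected posterior probability

eₙ is the mean, over the same predictive simulation, of
P(δ < δ* | data) itself rather than of the significance indicator. At
n = 0 with a fixed margin no simulation is needed: e₀ is exactly the
analysis prior's probability of non-inferiority, so an analysis prior
already carrying ≥ target support returns n = 0 ("no patients
needed"). Because only the mean of the posterior-probability
distribution is controlled — not its spread — eₙ-based sample sizes are
smaller than predictive-power ones whenever the design prior supports
non-inferiority.

## Precision and ACCEPT

The precision route uses analysis priors only (design priors are
deliberately not incorporated). At an assumed observed failure
proportion p per arm, the posterior at sample size n is taken as
Beta(a_A + np, b_A + n(1−p)) — fractional pseudo-counts — and the
100(1−α)% credible-interval width for δ is the closed form
2 Z_{α/2} √(V₁ + V₀). `p1_assumed`/`p0_assumed` are required explicit
inputs rather than defaulting to the analysis-prior means, because both
usages are legitimate: informative priors are naturally evaluated at
their own means, while flat Beta(1,1) priors (mean 50%) are evaluated
at the anticipated event rates. The CLI exposes
`--p-from design|analysis|value`.

ACCEPT curves plot P(δ > threshold | data) = 1 − Φ((t − μ_δ)/σ_δ)
against an ascending threshold grid; the curve passes through 0.5 at
the posterior mean exactly, and its maximum slope (over a window
containing the posterior mean) grows with n. Both computations are
deterministic; no seeds are involved.

## Frequentist comparator

n = (Z_{α/2} + Z_β)² [π₁(1−π₁) + π₀(1−π₀)] / (π₁ − π₀ − δ*)², equal
allocation, rounded to the **nearest** integer (half away from zero):
ceiling would give 311/552 and floor 198 where the conventional printed
values at 18% failure are {1241, 551, 310, 199, 138} for margins
{5, 7.5, 10, 12.5, 15}% — nearest reproduces all five. An attrition
helper inflates n by ⌈n/(1−loss)⌉. Designs with margin ≤ expected
difference raise `InfeasibleDesignError`.

## Monte Carlo and search conventions

- Default 100 000 replicates per estimate; binary-proportion standard
  error √(p̂(1−p̂)/reps), sample-SD standard error for eₙ. Every
  stochastic result carries (reps, seed).
- Draw order per replicate set is π₁, π₀, r₁, r₀, then δ*; a fixed
  margin consumes no random state, so a degenerate Uniform(δ*, δ*)
  margin reproduces the fixed-margin run bit-for-bit at the same seed.
- Sample-size searches scan an arithmetic grid (default step 10 on
  [10, 2000]; the expected-posterior search may start at 0) reusing
  one seed at every grid point (common random numbers), which removes
  the design-prior component of between-point noise. If the first
  grid point meeting the target is within one MC standard error of
  it, the two bracketing points are re-estimated once at tenfold
  replicates before the decision — the printed answers of interest sit
  close to their targets, and without escalation the search would
  flip-flop between adjacent steps.
- Grid searches that exhaust their range raise `SearchNotFoundError`
  carrying the best (n, estimate) seen.
- Moment matching Beta parameters from (mean, sd) is real-valued by
  default; integer rounding is opt-in (`round_params`), reproducing
  conventionally reported integer priors such as Beta(66, 302) for
  mean 18%, SD 2%.

## Bundled scenarios

`odyssey-base` encodes the worked example: design priors Beta(66, 302)
per arm (mean 18%, SD 2%, effective sample size 368), flat Beta(1, 1)
analysis priors, fixed 10% margin, α = 0.05. Variants:
`odyssey-degenerate-design` (Beta(6600, 30200) design priors — SD 0.2%,
recovering the frequentist calculation), `odyssey-enthusiastic`
(Beta(11, 48) analysis priors, prior NI probability 92%),
`odyssey-skeptical` (experimental Beta(141, 362), mean 28%; control
Beta(66, 302)), and Uniform(8%, 12%) / Uniform(5%, 15%) margin priors.
These are design scenarios, not data: the simulation engine generates
all "trial results" internally from the stated priors, so what the
tests demonstrate is internal consistency of the design calculations
under the stated models — not robustness to real-data features such as
non-exchangeable arms, drift in event rates, or margin opinions more
structured than a uniform interval.

## Numerical notes and limitations

- At 100 000 replicates a power estimate near 0.9 has MC standard
  error ≈ 0.001; the escalated boundary runs reach ≈ 0.0003. Searches
  whose true boundary value sits within ~0.001 of the target can still
  land one grid step high or low (the skeptical-prior power search is
  such a case: power at 760 per group is ≈ 0.8993, so the search
  legitimately returns 760 or 770 depending on the seed).
- The joint + wrong = unconditional identity is exact in counts;
  tests compare the float ratios at 10⁻¹² to allow for division
  rounding.
- Equal allocation only; risk-difference scale only; conjugate Beta
  priors only (priors placed directly on δ would require non-conjugate
  simulation and are out of scope). The precision route does not
  average over design priors.
- Searches assume the estimated quantity is non-decreasing in n over
  the grid, which holds for designs whose design-prior mean difference
  lies below the margin; strongly inferiority-favouring design priors
  can break monotonicity and should be searched with wider grids and
  inspection of the full curve.
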