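# bayesni

Bayesian sample size determination for **non-inferiority trials with
binary outcomes**, for trial statisticians planning a study whose
primary analysis will be Bayesian.

A non-inferiority trial tests whether a new treatment's failure risk is
not unacceptably higher than control's. On the risk-difference scale
with δ = π₁ − π₀ (experimental minus control failure probability) and a
positive margin δ*, the null hypothesis is δ ≥ δ*, and a *significant
Bayesian result* is a posterior probability of non-inferiority
exceeding 1 − α/2:

    P(δ < δ* | data) > 1 − α/2.

Each arm's failure probability gets a conjugate Beta prior, in two
roles: a **design prior** (planning-stage uncertainty about the true
rates, used to average operating characteristics) and an **analysis
prior** (the one the trial's Bayesian analysis will actually use). The
risk-difference posterior is approximated as normal with mean and
variance from the exact Beta posterior moments. Three Bayesian routes
to a per-group sample size n are implemented, plus the frequentist
comparator:

1. **Predictive power (assurance)** — the joint probability, over
   design priors π ~ Beta and data r ~ Bin(n, π), that the analysis is
   significant *and* the conclusion is correct (π₁ − π₀ < δ*),
   estimated by Monte Carlo. The margin may itself carry a Uniform
   prior representing variability of expert opinion.
2. **Expected posterior probability** — eₙ = E[P(δ < δ* | data)] over
   the predictive distribution of the data; controls the mean of the
   posterior probability rather than the chance of a significant
   result, and typically needs fewer patients.
3. **Precision / ACCEPT** — the closed-form 95% credible-interval width
   for δ as a function of n, and ACCEPT curves (posterior probability
   that δ exceeds a threshold, across thresholds); deterministic, uses
   analysis priors only.
4. **Frequentist** — n = (Z_{α/2} + Z_β)² [π₁(1−π₁) + π₀(1−π₀)] /
   (π₁ − π₀ − δ*)² with nearest-integer rounding.

## Worked example

The bundled scenarios reproduce the design of a paediatric HIV
non-inferiority trial: 18% anticipated failure in both arms, a 10%
margin, two-sided α = 0.05. Design priors Beta(66, 302) per arm (mean
18%, SD 2%, effective sample size 368); flat Beta(1, 1) analysis
priors.

```bash
$ bayesni freq-n --p1 18% --p0 18% --margin 10% --loss 10%
{
  "n_per_group": 310,
  "n_per_group_after_loss": 345,
  "n_total": 620,
  "n_total_after_loss": 690
}
```

310 per group gives 90% frequentist power. The Bayesian operating
characteristics of that same trial:

```python
>>> import bayesni as b
>>> base = b.load_scenario("odyssey-base")
>>> res = b.predictive_power(base, n_per_group=310, reps=200_000, seed=2026)
>>> round(res.joint_power, 3)
0.83
>>> b.find_n_for_power(base, target=0.90, reps=100_000, seed=2026)
440
>>> b.find_n_for_epp(base, target=0.90, reps=100_000, seed=2026)
110
```

Averaging over the design-prior uncertainty in the failure rates pulls
power at n=310 down from the frequentist 90% to 83% predictive power;
restoring 90% *predictive* power needs 440 per group. Controlling the
expected posterior probability of non-inferiority at 90% instead needs
only 110.

With a skeptical analysis prior (experimental Beta(141, 362), mean 28%;
control Beta(66, 302)), precision comes almost free from the prior:

```python
>>> sk = b.PrecisionInputs(b.BetaParams(141, 362), b.BetaParams(66, 302),
...                        p1_assumed=141/503, p0_assumed=66/368)
>>> round(b.ci_width(sk, 0), 2), round(b.ci_width(sk, 350), 2)
(0.11, 0.08)
```

— an 11%-wide 95% credible interval before any data, narrowing to 8%
at 350 per group.

All subcommands: `freq-n`, `power`, `power-n`, `epp`, `epp-n`, `width`,
`width-n`, `accept`, `report`. Scenarios come from YAML/JSON files or
the bundled names (`bayesni power --scenario odyssey-base --n 310
--seed 1`); stochastic commands print the seed they used.

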