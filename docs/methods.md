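# Methods

## Model

The package treats a completed parallel-arm RCT with a dichotomous endpoint
as a mixture of three deterministic potential-outcome profiles: responders
(event under control, no event under treatment), non-responders (event under
both), and non-informative participants (event under neither). Two
assumptions make the category counts identifiable from the 2×2 summary table
alone:

1. **Exchangeability** — both arms are draws from the same population, so
   the control event rate R<sub>C</sub> = a/N<sub>C</sub> is also the
   untreated event rate of the experimental arm. Observed rates are treated
   as true rates.
2. **Superiority** — the experimental treatment is at least as good as the
   control. There is no "harmed-by-treatment" profile. When a table
   contradicts this (b exceeding the expected untreated events), the
   responder count is clamped at zero and a `HarmfulTreatmentWarning` is
   emitted rather than producing negative categories.

Under these assumptions the expected untreated events in the experimental
arm are a·N<sub>T</sub>/N<sub>C</sub>; the responder count there is the
shortfall relative to the observed b, its control-arm counterpart scales by
N<sub>C</sub>/N<sub>T</sub>, and the remaining categories follow by
subtraction. Ethical losses — participants whose enrolment cannot be offset
by a primary-outcome benefit — are everyone except the experimental-arm
responders: (N<sub>C</sub> + N<sub>T</sub>) − (R<sub>C</sub> − R<sub>T</sub>)·N<sub>T</sub>.

The efficacy test is the standard Pearson chi-square on the 2×2 table
(df = 1, expected counts from the margins), with no continuity correction by
default and a Yates-corrected variant behind a flag; the p-value is the
upper chi-square tail. A zero margin raises rather than returning a
statistic that is not defined.

## Rounding

Counts of people must be integers. The package rounds **once, at the final
count**, never at intermediate rates, using round-half-away-from-zero
(`"half-up"`); banker's rounding is available as `"bankers"` through every
config. The canonical route for the treated-arm responder count is
round(expected untreated events) − b, which on the seed table equals the
algebraic round((R<sub>C</sub> − R<sub>T</sub>)·N<sub>T</sub>) route
(390 − 269 = 121 = round(120.75)); the seed counts 390 / 121 / 60 are
insensitive to the choice between the two rounding rules.

## The sweep

`run_sweep` reconstructs a family of hypothetical trials indexed by the
responder proportion p on the grid 0.025 … 1.0 in steps of 0.025 (40
trials; p = 0 is excluded because the sample size diverges). Held fixed
across the family, at their seed-trial values by default:

| parameter | default | meaning |
|---|---|---|
| `responders_T_fixed` | 121 | experimental-arm responder subgroup |
| derived C counterpart | 60 | 121 scaled by the seed arm ratio, fixed across the family |
| `arm_ratio` | 4687/7020 | experimental share of enrolment (≈2:1) |
| `Rc_unnecessary` | 194/2333 | untreated event probability of unnecessary participants |

At each p: total responders R = 121 + 60; N = R/p; arms split by
`arm_ratio`; every control-arm potential responder presents the event; every
unnecessary participant presents it with probability `Rc_unnecessary` in
both arms. Each reconstructed table then passes through the same
decomposition and chi-square operations as observed data. At p = 1 the
family collapses to the "perfect" all-responder trial (60 controls all with
the event, 121 treated all event-free, ethical losses 60); at p = 0.025 the
sample exceeds 7000.

"Rc remained constant" is implemented as the *parameter*
`Rc_unnecessary` being constant, not the observed control rate — the
observed rate cannot be constant, since it reaches 1 in the perfect trial.

**Rounding jitter and trend verdicts.** Before rounding, the family is
smooth: N(p) = R/p, the ethical-loss share 1 − p·121/R is exactly linear in
p, the relative risk falls monotonically and the chi-square rises
monotonically. Rounding counts to whole participants leaves N and the loss
share monotone, but the experimental event count shrinks to single digits as
p → 1 and its integerization wiggles RR by up to ~8×10⁻⁴ and the chi-square
by up to ~3 at a handful of grid points. Each `SweepRow` therefore carries
both the rounded-table metrics (what a real trial of those integer counts
would show, and what the CSV reports) and the continuous-model metrics;
`trend_check` evaluates its monotonicity verdicts and R² on the continuous
series and reports the largest adverse rounded-series step as
`max_rounding_jitter`, so the size of the artifact is always visible.
Degenerate (constant) series get R² = None rather than a fabricated fit.

## The synthetic cohort generator

`generate` draws N participants with iid latent profiles
(responder with probability `p_responder`, non-responder with
`p_nonresponder`, otherwise non-informative), iid Bernoulli(`alloc_T_share`)
arm assignment (an exact-split permutation variant is available for matching
fixed margins), and deterministic potential outcomes per profile; the
realized outcome is the potential outcome of the assigned arm. Defaults
emulate the seed trial: N = 7020, ≈2.6% responders, ≈5.7% non-responders,
2:1 allocation. Replicates use sub-streams spawned from a single root seed
by replicate counter (`SeedSequence(entropy=seed, spawn_key=(rep,))`), so
any replicate is reproducible in isolation and experiments parallelize by
contract.

This generator is the exact generative counterpart of the decomposition:
E[R<sub>C</sub>] − E[R<sub>T</sub>] = `p_responder` identically, so
`recovery_experiment` checks the calculus by Monte Carlo — the mean error of
the absolute-benefit estimator against `p_responder`, and of the
decomposition's treated-responder count against the latent tally, each with
its standard error and a 3-SE bias flag.

What the generator deliberately does **not** emulate: covariates and
between-participant risk heterogeneity, dropout, non-compliance,
misclassification, and any harmed-by-treatment profile. Passing recovery
tests therefore show the decomposition is self-consistent under its own
assumptions — not that those assumptions hold in any real trial, where
untreated risk varies between participants and arms are only exchangeable
on average.

## Numerical choices and edge cases

- Relative risk is `None` (and `relative_risk` raises) when no control
  events occurred, instead of a silent zero.
- Arm sizes in the sweep are forced to sum to N by giving the rounding
  remainder to the control arm; grid points that would push an arm below
  its fixed responder subgroup raise `InfeasibleGridPointError`.
- Negative category counts during decomposition raise a
  `DecompositionError` naming the offending category.
- Config files are strict JSON (unknown keys rejected, pydantic-validated);
  table files are JSON cells `a,b,c,d` or two-row `arm,events,no_events`
  CSV with line-anchored error messages.
- The recovery experiment at its test scale uses 200 replicates of
  N = 10,000 (seconds of runtime); the large-cohort consistency check uses a
  single N = 200,000 cohort.

## Known limitations

- The calculus reads observed rates as true rates; in small trials the
  "counts" it returns inherit binomial noise and the responder count can be
  clamped at 0 by chance even under a truly beneficial treatment.
- Only dichotomous endpoints are supported; continuous or time-to-event
  outcomes are out of scope, as are confidence intervals for the effect
  measures and conventional power/sample-size planning.
- The sweep's reconstruction holds the control-arm potential-responder
  subgroup fixed at its seed value (60) rather than re-deriving it per grid
  point; this is the one choice consistent with the perfect-trial limit.
- A stratified (cluster-wise) generator with varying responder proportions
  is a natural extension and is not implemented.
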