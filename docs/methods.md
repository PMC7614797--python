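# Methods

## Data-generating process

One simulated trial is built in five steps, in enrollment (index) order:

1. **True covariate.** `X_i ~ Bernoulli(π)`, iid. Default `π = 0.5`;
   the sensitivity grid uses 0.75.
2. **Misclassification.** Each participant's stratum flag is flipped
   independently with probability `p0` (if `X = 0`) or `p1` (if `X = 1`),
   producing the randomisation stratum `Z`. Under the *equal* pattern
   `p0 = p1 = e` (the overall error rate). Under the *unequal* pattern the
   rate is three times higher in the more common stratum while the
   prevalence-weighted average is preserved: for `π ≥ 0.5`,
   `p0 = e/(1+2π)`, `p1 = 3·p0` (so `(0.1, 0.3)` at `e = 0.2, π = 0.5` and
   `(0.08, 0.24)` at `π = 0.75`); the mirror-image solution is used when
   `π < 0.5`. A derived rate above 1 makes the scenario infeasible and is
   rejected at configuration time. Errors precede allocation and are
   therefore independent of treatment by construction.
3. **Randomisation.** Within each stratum of `Z`, participants are assigned
   from consecutive, independently permuted blocks containing
   `block_size/2` of each arm (default blocks of 4, 1:1 allocation). Blocks
   are generated on demand and the final block may be incomplete, so the
   within-stratum arm imbalance never exceeds `block_size/2` at any point
   in the enrollment sequence. An empty stratum is simply skipped. No
   rebalancing is attempted across strata.
4. **Error discovery.** Each *error* is discovered independently with an
   arm-specific probability: equal pattern `d0 = d1 = d`; unequal pattern
   `d0 = d/2`, `d1 = 3d/2` (valid for 1:1 allocation; `(0.25, 0.75)` at
   `d = 0.5`); *all* pattern `d = 1`. Correct records can never be
   "discovered" — `W` equals `X` where the record is correct or corrected
   and `Z` where an error survives. One uniform variate is drawn per
   participant (not per error) so the random stream's length does not
   depend on the error configuration.
5. **Outcomes.** `Y_i = α + β_T·T_i + β_X·X_i + β_TX·T_i·X_i + e_i` with
   standard-normal residuals. Outcomes depend on the true stratum only;
   `Z` and `W` affect `Y` only through the blocking of the allocation.

## Estimands and analyses

All analyses are OLS with 0/1-coded covariates (not centred):

- **Treatment effect.** `Y ~ 1 + T (+ C)` with `C ∈ {∅, Z, X, W}`. The
  treatment coefficient targets `E[Y(1) − Y(0)]`, whose true value is
  `β_T` when `β_TX = 0`.
- **Interaction.** `Y ~ 1 + T + C + T·C` with `C ∈ {Z, X, W}`. The
  interaction coefficient targets the difference in subgroup effects
  (true value `β_TX`); with 0/1 coding the treatment coefficient is the
  subgroup effect in stratum `C = 0` (true value `β_T`).
- **Marginal effect ignoring an interaction.** The main-effects model fitted
  to data generated with `β_TX ≠ 0`; the estimate is judged against the
  average treatment effect across strata, `β_T + π·β_TX`.

Joint adjustment for `Z` and `X` in one model is deliberately not offered:
the two are nearly collinear at low error rates and the design would be
numerically singular exactly where the comparison is most interesting.

Inference is classical: `σ̂² = RSS/(n−p)`, `V̂ = σ̂²(D'D)^{-1}`, 95%
intervals and two-sided 5% tests from the t distribution on `n−p` degrees of
freedom (the default of mainstream regression software). At `n = 1000` this
is indistinguishable from normal inference; at the `n = 200` sensitivity
setting it matters slightly. The same critical value is used for the
interval and the test, so "reject" is exactly "interval excludes zero".
The design matrix is solved by QR; a diagonal element of `R` below
`n·eps` times the largest triggers a `SingularDesignError` naming the
offending column(s). In study runs, repetitions with singular designs
(possible only in very small trials, e.g. an empty treatment-by-stratum
cell) are dropped with a logged count and `n_reps_used` reduced.

## Performance measures and Monte Carlo SEs

For R repetitions of one (scenario × method × parameter) cell with
estimates `β̂_j`, model variances `v̂_j`, rejection and coverage indicators:

| measure | definition | MCSE |
|---|---|---|
| bias | `mean(β̂) − β_true` | `EmpSE/√R` |
| EmpSE | `sd(β̂)` (denominator R−1) | `EmpSE/√(2(R−1))` |
| ModSE | `√(mean(v̂))` | — |
| relative % error | `100·(ModSE/EmpSE − 1)` | delta method (below) |
| coverage % | % of 95% CIs containing `β_true` | `100·√(p̂(1−p̂)/R)` |
| rejection % | % of 5% tests rejecting | `100·√(p̂(1−p̂)/R)` |

The relative-error MCSE combines the sampling variance of ModSE (from the
spread of the `v̂_j`) with that of 1/EmpSE, treated as independent:
`100·(ModSE/EmpSE)·√( S²(v̂)/(4·R·ModSE⁴) + 1/(2(R−1)) )`. When
`EmpSE = 0` the relative error is undefined and reported as NaN (with a
warning if ModSE is positive).

The **arm-mean correlation** is the Pearson correlation, across
repetitions, of the control- and intervention-arm sample means of `Y`; its
Monte Carlo SE on the Fisher-z scale is `1/√(R−3)` (≈ 0.01 at R = 10,000).

**Analytic design checks** use the exact noncentral-t distribution: the
two-sample t-test power at 500/arm, δ = 0.2 SD, α = 0.05 is 88.5%; the
balanced 2×2 interaction contrast (SE `= σ·√(4/n_cell)`, 250/cell) has
35.2% power at `β_TX = 0.2` and 88.5% at 0.4.

## Scenario grid and orchestration

Eight study sections enumerate 122 scenarios (18 correlation, 16 full
discovery, 4 no-error reference, 32 partial discovery, 12 + 24 interaction,
8 + 8 sensitivity), each a deterministic cross-product of the section's
factors over the defaults `n = 1000`, `π = 0.5`, `α = 0`, blocks of 4,
`R = 10,000`. Scenario identifiers are stable hashes of the parameter
tuple, so identical scenarios appearing in two sections share an id and
results are joinable across runs.

**Random numbers.** Each scenario draws from a `SeedSequence` derived from
`(master seed, scenario id)`, so results are independent of execution order
and of the worker count used for scenario-level parallelism, and any
scenario can be reproduced in isolation. Within a repetition, every
requested analysis sees the same simulated dataset (common random numbers),
which is what makes within-scenario method comparisons tight.

## What the generator does and does not emulate

It emulates the mechanics that drive the phenomenon under study: blocked
allocation within misclassified strata, error rates that may differ by
stratum, and discovery that may differ by arm. It does not emulate features
of real trials that are orthogonal to that mechanism — staggered or
informative enrollment, missing outcomes, non-normal or heteroscedastic
residuals, multiple stratification factors, >2 strata, or non-1:1
allocation. Results here therefore quantify the misclassification mechanism
in isolation; calibration statements (e.g. "coverage is nominal") transfer
to real data only insofar as the linear model is adequate.

## Numerical and testing choices

- The test suite reruns the pipeline at reduced replication (2000–3000
  repetitions for headline rejection rates and correlations, 500 for the
  full-discovery bias/coverage sweep) and uses tolerances of three times
  the Monte Carlo SE implied by the rep count actually run. The acceptance
  script (`scripts/acceptance.py`) runs the full 10,000 repetitions.
- The bias/coverage sweep asserts ~60 cells simultaneously; a raw 3-sigma
  band per cell would false-alarm ~12% of the time by construction, so
  those sweeps use a Sidak-style familywise multiplier of 3.9 chosen a
  priori to keep the suite's overall false-alarm rate near the
  single-comparison 3-sigma convention.
- Rejection decisions use strict inequality `|β̂| > t_crit·SE`; with a
  perfect fit (zero residuals) the interval collapses to the point estimate
  and a zero estimate is not rejected.
- `error_rate = 0` and `discovery_rate ∈ {0, 1}` are honoured exactly
  (`Z ≡ X ≡ W`, `W ≡ Z`, `W ≡ X` respectively) and are tested as
  degenerate cases.

## Known limitations

- Only 1:1 allocation is supported; the unequal-discovery construction
  `(d/2, 3d/2)` presumes equal arm sizes.
- Robust/sandwich variance estimators are not provided (they matter mainly
  under unequal allocation, which is out of scope).
- A single binary stratification factor; minimisation and other
  covariate-adaptive schemes are out of scope.
- Figure rendering is not built in; summaries are tidy CSVs intended for
  downstream plotting.
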