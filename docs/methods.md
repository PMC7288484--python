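# Methods

## Scope and model structure

`adaptrial` estimates frequentist operating characteristics of Bayesian
adaptive two-arm superiority designs by direct simulation. Two endpoint
models are implemented; both are fully conjugate, so every posterior
quantity is available in closed form and the simulators never need MCMC.

### Time-to-event endpoint (log hazard ratio summary)

The trial is represented at the *analysis* level. At a look with `d`
events under 1:1 allocation, the estimated log hazard ratio is modelled as

    theta_hat ~ N(log HR_true, c/d),   c = 4 by default,

the standard large-sample variance of a log-HR estimator with equal
allocation and equal follow-up (`variance_factor` exposes `c` for other
allocation ratios). With the vague prior `log HR ~ N(0, 10000)` the
posterior is normal with precision-weighted mean, and decision rules act
on `Pr(HR < 1 | data)`. No survival times, censoring or accrual are
simulated for this endpoint; that is the model's point, not a shortcut —
the monitored statistic's sampling distribution is specified directly.

**Look dependence.** Two modes:

* `independent` (default): the interim and final estimates are drawn
  independently. The default exists because the package's reference
  results — a 19% type I error for the two-look efficacy design with 0.9
  bars, dropping to 9.75% with 0.95 bars — are exactly the independence
  arithmetic `1 - b^2`, and the closed-form oracle
  (`analytic_success_probability`) assumes it.
* `correlated-increments`: the canonical group-sequential structure. The
  score statistic `S_k = I_k * theta_hat_k` with Fisher information
  `I_k = d_k / c` accumulates as `S_final = S_interim + increment` with an
  independent `N((I_f - I_i) mu, I_f - I_i)` increment, giving
  `corr(theta_hat_i, theta_hat_f) = sqrt(I_i / I_f)`. No closed-form
  success probability is provided in this mode; the simulator is the
  estimator.

The closed-form oracle inverts the conjugate update exactly (including the
prior's shrinkage, which is O(1e-5) at these variances), so simulation and
closed form agree to Monte-Carlo error, and the expression reduces to
`Phi(Phi^{-1}(1 - b) - log HR / sqrt(c/d))` per look in the flat-prior
limit.

### Binary endpoint (patient level)

Patients arrive under deterministic accrual at `accrual_rate`/day
(default 2), are allocated 1:1 in permuted blocks of two, and yield a
Bernoulli outcome with their arm's true rate, observable `followup_days`
(default 28) after enrolment. At an interim after `n` recruited patients,
exactly `floor(followup_days * accrual_rate)` of them (56 at the defaults)
lack completed follow-up.

Each arm's rate has a `Beta(1, 1)` prior — the canonical uniform; at
per-arm sample sizes in the hundreds any other near-flat choice is
immaterial, and the shapes are configurable. Superiority is
`Pr(theta_int < theta_ctrl | data)` for the two independent beta
posteriors, computed exactly (below).

**Predictive stopping rules.** `P_curr` imputes only the
enrolled-but-incomplete patients from the current posteriors
(`n_imputations` beta-binomial draws, default 500) and reports the
fraction of completions in which the final success rule already holds at
the current enrolment. `P_max` additionally imputes all not-yet-enrolled
patients up to the per-arm maximum and evaluates success at the maximum
sample size. A fully observed state returns the exact 0/1 indicator.
Efficacy stops when `P_curr` exceeds its bar, futility when `P_max` falls
below its bar; all comparisons are strict, so bars of exactly 1 (efficacy)
or 0 (futility) are accepted as well-defined never-firing rules. If both
rules are active at one look, efficacy is evaluated first (simultaneous
triggering is practically impossible: it would need `P_curr > 0.99` and
`P_max < 0.10` at once).

**Exact superiority probability.** For integer-shape posteriors,
`Pr(theta_int < theta_ctrl)` uses the exact finite-sum identity
(summing over the control shape, evaluated in log space); for non-integer
shapes it falls back to adaptive quadrature of
`int_0^1 F_int(F_ctrl^{-1}(u)) du`, a bounded monotone integrand immune to
endpoint singularities, with absolute tolerance 1e-10 and a canonical
orientation that makes `p(A,B) + p(B,A) = 1` hold exactly.

**Critical-boundary caching.** Inside the predictive computations, an
imputed completion is a success iff the intervention event count is at
most a critical value that depends only on (per-arm totals, control event
count, threshold, prior). That boundary is monotone in the control count's
complement, found once by bisection over the exact superiority
probability, and memoised. This turns hundreds of imputations into a
vectorised table lookup and is exact — a performance device, not an
approximation; the package's 10^4-trial runs with 500 imputations per look
complete in well under a minute on one CPU.

## Randomness and reproducibility

All randomness derives from one master seed through `SeedSequence` spawn
keys. Trial `i`'s patient stream is keyed `(seed, 0, i)` and its
imputation streams `(seed, 1, i, recruit_count)`. Consequences:

* results are bit-identical for a given seed, independent of batching;
* two designs run with the same seed share patient-level data (common
  random numbers), so paired comparisons (`compare_schedules`) have far
  smaller variance than independent runs;
* a look's predictive probability depends only on the data and the look's
  recruitment count — not on which other looks a design performs — so for
  *nested* interim schedules the success sets nest exactly, path by path:
  futility looks can only remove successes, efficacy looks can only add
  them. For non-nested schedules (e.g. the evenly spaced schedules of
  different interim counts) the same direction holds in expectation but
  not trial-by-trial, and the tests assert the exact property on nested
  schedules only.

## Calibration

`calibrate_threshold` simulates the per-look posterior summaries of the
null scenario once; a candidate threshold is then a pure filter over that
matrix, so the estimated type I error is a step function of the threshold
with no Monte-Carlo noise between candidates, and bisection returns the
least stringent threshold whose error is at or below target + tolerance.
A single stringency scalar is calibrated: for an efficacy design it
replaces both the interim and final bars (mirroring the 0.9 → 0.95
tightening), for a futility design only the final bar (the futility bar is
part of the design's identity). Degenerate targets are flagged rather
than raised: target 1 returns the search-space minimum, target 0 the
never-succeed threshold 1. For the binary endpoint, calibration supports
interim-free designs (filtering the per-trial final superiority
probability); designs with predictive interim rules are rejected, because
`P_curr`/`P_max` themselves depend on the final threshold and the
pure-filter premise breaks.

## Default problem sizes

The time-to-event engine is vectorised; its reference runs use 10^6
replications (< 2 s). The binary engine is patient-level; its reference
runs use 10^4 replications with 500 imputations per look (≈ 30 s for a
paired two-schedule run), matching the replication count a design report
at this scale would use. Reduced-scale designs (`n_max = 400`, 100
imputations, tens-to-hundreds of replications) are used in property tests
where the assertion is exact (path-wise nesting, determinism) rather than
statistical.

## What the generator does and does not emulate

Simulated data are idealised: deterministic accrual (the real quantity is
stochastic and unknown at design time — the rate is a stated assumption,
default 2 patients/day, and materially affects how many patients are
incomplete at each look and hence `P_curr`), exact 1:1 blocks, no
missingness by default (an optional uniform dropout removes patients from
numerator and denominator; interim analyses do not anticipate future
dropout), outcomes revealed exactly at the follow-up lag, and no drift in
event rates over calendar time. Passing tests therefore demonstrate the
decision-rule arithmetic and its frequentist consequences under the
stated generative assumptions, not robustness to the operational
complications of a real trial. Likewise the time-to-event model's `4/d`
variance is an approximation whose accuracy in a real trial depends on
censoring and allocation balance.

## Numerical choices

* Strict inequalities throughout, as the rules are written; a posterior
  probability exactly at the futility bar continues (a measure-zero event
  under both endpoint models).
* Even interim schedules round half up: `round(k * n_max / (K + 1))`,
  giving 334/667/1001 for three looks over 1334; schedules whose rounded
  looks collide are rejected.
* The exact finite superiority sum is used up to 20 000 terms, far beyond
  any trial-sized count; `logsumexp` guards against underflow.
* Calibration bisects on `[0.5, 1)` for at most 60 iterations or until the
  bracket is below 1e-12.

## Known limitations

* The closed-form time-to-event oracle exists only for independent looks.
* Binary-endpoint calibration excludes designs with predictive interim
  rules (see above); calibrating those requires re-simulating per
  candidate, which is out of scope.
* `P_curr`/`P_max` are Monte-Carlo estimates; their imputation-count error
  (binomial with `n_imputations` draws) is part of the simulated design,
  as it would be in any predictive-probability implementation.
* Response-adaptive randomisation, hierarchical/informative priors and
  decision-theoretic (utility-based) stopping are out of scope.
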