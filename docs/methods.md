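# Methods

## The model

`tssnmix` implements the binomial N-mixture model under time-for-space
substitution (TSS). A single population is surveyed `J` times per year for
`I` years. Within a year the population is assumed demographically closed,
so the years play the role that distinct sites play in the classical
meta-population N-mixture design, and the within-year surveys are the
closed-population replicates.

Latent abundance in year `i` follows a Poisson with a log-linear trend,

    N_i ~ Poisson(λ_i),      log(λ_i) = β0 + β1 · t_i,

and each survey count is a binomial thinning with constant per-individual
detection probability,

    C_ij | N_i ~ Binomial(N_i, p),      logit(p) = α0.

The year covariate is coded `t_i = i − 1`, so `exp(β0)` is the expected
abundance in the first year. This makes the "initial abundance" parameter of
a simulation scenario exactly the year-1 model prediction, and it makes the
abundance error metric below well defined. The same coding is used in the
simulator and the fitter; mixing codings would silently decouple the trend
estimate from its simulated truth.

The likelihood marginalises the latent abundances with a finite sum,

    ℓ(β0, β1, α0) = Σ_i log Σ_{N = max_j C_ij}^{K} Pois(N; λ_i) Π_j Bin(C_ij; N, p),

computed entirely on the log scale (log-gamma tables plus a log-sum-exp over
the latent grid). A brute-force probability-space enumeration of the same
double sum is kept in the test suite as an oracle; the production
implementation agrees with it to better than ten significant digits on
small matrices.

Two readings of "estimated abundance" are defensible for a trending
population: the year-1 prediction and the across-year mean prediction. The
package exposes the full trajectory (`predict` / `predict_abundance`) and
uses the year-1 prediction `N̂ = exp(β̂0)` as the headline abundance
estimate, because the evaluation compares against the scenario's initial
abundance.

## Truncation bound K

The infinite latent sum must be truncated at some bound `K`. Two policies
are exposed, and the distinction matters scientifically.

`K="auto"` (the default, and what the evaluation pipeline uses) is the
field's conventional automatic rule, `K = max(counts) + 100`. When
detection is weak or abundance large this bound can fall *below* the
fitted λ (λ = 100 with p = 0.1 gives counts near 10 and a bound near 120;
λ growing to ~670 under a +0.1 trend with p = 0.7 gives counts near 470
and a bound near 570). A clipped sum has two consequences: it biases
abundance down and detection up by roughly 10% in the worst design cells,
and — importantly for sparse, low-detection data — it *clamps* the
detection→0 likelihood ridge, so weakly identified fits terminate at
moderate abundance instead of running off to absurd values. The standard
monitoring workflow this package evaluates inherits both effects; results
produced under this rule characterise the procedure as practised, so the
simulation study runs it throughout.

`K="adaptive"` enlarges the bound (refitting from scratch — a quasi-Newton
warm start at the previous optimum can stall on the nearly flat
abundance/detection ridge before reacting to the new bound) until the
fitted Poisson mass above `K` is below 1e−10 per year. This keeps the
log-likelihood truncation error under ~1e−8 and makes the estimates stable
to doubling `K` (an invariant the test suite enforces for this mode). It
is the right mode when the estimates themselves are of interest — the
parameter-recovery tests use it — but on ridge datasets the unclamped
estimate grows without bound; a fit still demanding `K > 5000` is reported
as non-converged (`K_overflow`) rather than chased further.

An explicitly supplied integer `K` is always honoured unchanged.

## Optimisation, convergence and intervals

The three link-scale parameters are estimated with L-BFGS-B from heuristic
starts (α0 from the ratio of the mean to the maximum count, clipped to
[0.05, 0.95]; β0 from the mean of yearly maxima inflated by the initial
detection guess; β1 = 0), with up to five jittered restarts on failure.
Box bounds (β0 ∈ [−10, 20], β1 ∈ [−3, 3], α0 ∈ [−15, 15]) keep the search
away from overflow; an estimate within 1e−4 of a bound is reported as
non-converged (`estimate_at_bound`), since it indicates the detection → 0
ridge rather than an interior optimum.

The covariance is the inverse of a central-finite-difference Hessian of the
negative log-likelihood at the optimum (relative step 1e−4); a Hessian that
is not finite or not positive definite marks the fit non-converged with a
reason code. 95% intervals are Wald intervals on the link scales,
back-transformed: `exp` for abundance, logistic for detection, identity for
the trend. All-zero count matrices are reported as `all_zero_counts`
without fitting (abundance and detection are jointly unidentifiable there).

Non-converged fits are never silently dropped: they carry reason codes
through the record table, are excluded from summary statistics, and are
counted per scenario (`n_failed`).

## Goodness of fit

The fit diagnostic is a Pearson chi-square over all year × survey cells
with fitted cell expectation `E_ij = λ̂_i · p̂` (the marginal mean of a
count under the model — computable without imputing the latent states).
Its reference distribution comes from a parametric bootstrap: simulate a
dataset from the fitted parameters, refit it, and evaluate the statistic
under the replicate's own refit; the p-value is the fraction of bootstrap
statistics at least as large as the observed one, and the overdispersion
ratio is `ĉ = χ²_obs / mean(χ²_boot)`. A model is classified "good" when
p > 0.1 (strict). Bootstrap refits that fail to converge are dropped and
counted. The default `n_boot` is 200; 1000 is the conventional choice when
runtime permits.

## The simulation study

The evaluation layer reproduces a factorial estimator-evaluation design:

| factor | values | unit |
|---|---|---|
| trend β1 | −0.1, 0.0, +0.1 | per year, log scale |
| initial abundance N | 5, 20, 100 | individuals |
| study duration | 10, 20 | years |
| survey effort | 3, 5 | surveys/year |
| detection p | 0.1, 0.3, 0.5, 0.7 | probability |

giving 144 scenarios (48 per trend level). Scenario ids enumerate the
Cartesian product with trend outermost and detection probability innermost,
so a configuration always maps to the same id. Per-dataset seeds derive
from `SeedSequence([base_seed, scenario_id, rep_index])`, making every
dataset regenerable in isolation and the whole run independent of worker
scheduling.

Per-dataset metrics:

* **N-error** = (N̂ − N) / N, with N the scenario's initial abundance.
* **T-error** = (T̂ − T) / T for trending scenarios; for constant
  populations (T = 0) the raw distance T̂ − T is used.
* **Coverage** flags: whether the 95% CIs for N̂ and T̂ contain the true
  N and β1.
* **Abundance heterogeneity**: the coefficient of variation of the true
  yearly abundances, `sd(N_i)/mean(N_i)`, with the sample (n−1) standard
  deviation (the denominator convention is not standardised in the
  literature; n−1 is the package's choice and matters little at 10–20
  years).

Cross-scenario summaries: scenarios are split by whether their
abundance-CI coverage rate reaches 0.95, per-dataset N-errors pooled within
each group, and the groups compared with a two-sided Mann–Whitney test
(normal approximation, tie-corrected). The coverage split is computed over
all scenarios with the threshold configurable; which scenarios a particular
published analysis included in its coverage subset is typically not
enumerable, so pooled group means should be expected to reproduce only
approximately. Heterogeneity is related to the absolute abundance error by
Spearman rank correlation over constant-trend datasets.

Per-dataset units enter the covered/uncovered comparison, grouped by
scenario-level coverage; a per-scenario-means variant can be obtained by
aggregating the record table first (`summarize_records`).

## What the generator does and does not emulate

The simulator draws independent Poisson abundances around a deterministic
log-linear trend and independent binomial counts. It therefore emulates
*unmodelled abundance heterogeneity* only of the Poisson kind (quantified
by the CV metric above). It does not emulate: serial dependence of
abundance (no survival/recruitment dynamics), within-year closure
violations, individual or temporal heterogeneity in detection,
double-counting, or negative-binomial overdispersion. Passing tests
therefore certify estimator behaviour when the model is correctly
specified — they say nothing about robustness to closure or detection
assumption violations in field data.

## Problem sizes and numerical choices

The package's reference evaluation runs the 144-scenario grid at 100
replicate datasets per scenario (14,400 fits, a few minutes on one core);
published studies of this design have used 1000 replicates per scenario,
which the same code reproduces given proportionally more time
(`n_reps` in the config). The goodness-of-fit calibration runs use 200
outer replicates at 200 bootstrap resamples, matching the reduced
replication that is conventional for nested-bootstrap analyses. Spearman
and Mann–Whitney statistics at these sizes carry Monte-Carlo standard
errors of roughly 0.015 and group-mean uncertainties dominated by scenario
composition; the acceptance tests use three empirical standard errors as
their tolerance.

Known limitations: Wald intervals on the link scale can be poor near the
detection ridge (small N, small p), where coverage of the abundance
interval degrades — that degradation is itself one of the study's findings,
not an artifact; the abundance estimate is the year-1 prediction, so its
error metric inherits any trend-estimation error at long horizons; and the
negative-binomial mixture variant is deliberately out of scope.
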