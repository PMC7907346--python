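# tssnmix

Binomial N-mixture models with **time-for-space substitution (TSS)**:
estimating the abundance and trend of a *single* population from repeated
counts, plus a full simulation framework for evaluating how reliable those
estimates are.

Classical N-mixture models need spatial replication — repeated counts at
many sites — to separate abundance from imperfect detection. Many
monitoring programs have only one population (one site) surveyed a few
times per year over many years. TSS swaps the roles: years act as the
replicate units, within-year surveys as the closed-population replicates.
The model is

```
N_i ~ Poisson(λ_i),        log(λ_i) = β0 + β1 · t_i        (t_i = i − 1)
C_ij | N_i ~ Binomial(N_i, p),   logit(p) = α0
```

where `N_i` is the latent abundance in year `i`, `C_ij` the count in survey
`j` of year `i`, and `p` the per-individual detection probability. Fitting
maximises the marginal likelihood (latent abundances summed out up to a
truncation bound `K`), giving the initial abundance `N̂ = exp(β̂0)`, the
log-linear trend `T̂ = β̂1`, and `p̂`, with Wald 95% intervals.

The package is written for quantitative ecologists and biostatisticians who
want to (a) fit TSS N-mixture models to their own count matrices, (b) check
fit adequacy with a parametric-bootstrap goodness-of-fit test, and (c)
quantify — by simulation — how estimation error, confidence-interval
coverage and GOF behaviour depend on population size, trend direction,
detection probability, study length and survey effort.

## Worked example

```python
import numpy as np
from tssnmix import ScenarioSpec, simulate_dataset, TSSNMixture, bootstrap_gof

# a declining population: 100 individuals, 10% yearly decline on the log
# scale, 20 years x 5 surveys, detection probability 0.5
scenario = ScenarioSpec(trend_coeff=-0.1, initial_abundance=100,
                        n_years=20, n_surveys=5, detection_prob=0.5,
                        n_reps=1, base_seed=42)
data = simulate_dataset(scenario, rep_index=0)

model = TSSNMixture().fit(data.counts)
print(f"N_hat = {model.n_hat_:.1f}  (95% CI {model.n_hat_ci_[0]:.1f}-{model.n_hat_ci_[1]:.1f})")
print(f"T_hat = {model.t_hat_:.3f} (95% CI {model.t_hat_ci_[0]:.3f}-{model.t_hat_ci_[1]:.3f})")
print(f"p_hat = {model.p_hat_:.2f}")

gof = bootstrap_gof(data.counts, model.result_, n_boot=200, seed=1)
print(f"GOF p = {gof.p_value:.2f}, c-hat = {gof.c_hat:.2f}")
```

Output:

```
N_hat = 92.7  (95% CI 70.9-121.1)
T_hat = -0.106 (95% CI -0.120--0.092)
p_hat = 0.57
GOF p = 0.86, c-hat = 0.77
```

The true values (N = 100, T = −0.1, p = 0.5) sit inside every interval:
the fitted trend says the population loses about 10% per year on the log
scale, initial abundance is estimated at ~93 against a truth of 100, and
the bootstrap GOF test finds no lack of fit (p > 0.1, ĉ near 1).

`TSSNMixture` is a scikit-learn-style estimator (`get_params`/`set_params`,
`fit`, `predict` for the yearly abundance trajectory); functional wrappers
(`fit_tss`, `marginal_loglik`, `predict_abundance`, …) expose the same
machinery.

## The simulation study

`tssnmix.evaluation` builds a factorial grid over trend ∈ {−0.1, 0, +0.1},
initial abundance ∈ {5, 20, 100}, duration ∈ {10, 20} years, effort ∈
{3, 5} surveys/year and detection ∈ {0.1, 0.3, 0.5, 0.7} — 144 scenarios —
simulates replicate datasets for each, fits every one, and reports
N-error = (N̂ − N)/N, T-error, CI coverage, abundance heterogeneity (the
CV of true yearly abundances) and their cross-scenario summaries
(covered-vs-uncovered Mann–Whitney split, heterogeneity–error Spearman
correlation). The same pipeline is scriptable from the shell:

```bash
tssnmix evaluate --config config.yaml --out results/
tssnmix simulate --config config.yaml --out datasets/
tssnmix fit datasets/scenario0000_rep0000_counts.csv
tssnmix gof  datasets/scenario0000_rep0000_counts.csv --n-boot 200
```

See `docs/methods.md` for the model, the truncation-bound policies, error
metrics and the design choices behind the evaluation.

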