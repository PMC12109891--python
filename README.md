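# pglogit

Bayesian random-intercept panel logit modelling for binary survey
outcomes, via Pólya–Gamma-augmented Gibbs sampling with
ancillarity–sufficiency interweaving (ASIS).

The package targets the analysis workflow of long-running household panel
surveys in which a binary well-being indicator (here: whether a
respondent reports having something to live for) is observed for each
respondent over up to nine annual waves, together with demographic dummy
blocks (spouse, sex, year, age band, region, city size) and quantitative
items (life-satisfaction scores on a centred −5..+5 scale, monetary
amounts on a log1p scale). It is written for applied biostatisticians and
survey methodologists who need the full pipeline — simulation, respondent
filtering, imputation, MCMC estimation, model comparison — as tested,
composable pieces.

## Model

For respondent $r = 1,\dots,R$ observed in waves $t = 1,\dots,T_r$:

$$y_{rt} \sim \mathrm{Bernoulli}(\pi_{rt}), \qquad
\pi_{rt} = \frac{e^{\psi_{rt}}}{1 + e^{\psi_{rt}}}, \qquad
\psi_{rt} = \alpha_r + x_{rt}'\beta,$$

with respondent-level intercepts and conjugate hierarchy

$$\alpha_r \sim N(\mu_\alpha, \sigma_\alpha^2),\quad
\beta \sim N(\mu_\beta, A_\beta^{-1}),\quad
\mu_\alpha \sim N(\mu_0, \sigma_0^2),\quad
\sigma_\alpha^2 \sim \mathrm{IG}(\tfrac{\nu_0}{2}, \tfrac{\lambda_0}{2}).$$

There is no global intercept: the $\alpha_r$ absorb the level. Pólya–Gamma
augmentation ($\omega_{rt} \mid \cdot \sim \mathrm{PG}(1, \psi_{rt})$)
renders every full conditional Gaussian or inverse-gamma, so the model is
fitted by exact Gibbs sampling; an ASIS interweaving move re-updates
$(\mu_\alpha, \sigma_\alpha^2)$ in the non-centred parameterization each
sweep, which makes the hyperparameters mix well even with thousands of
weakly-identified intercepts. Model comparison uses WAIC computed from
stored pointwise log-likelihoods; convergence is monitored with split
Gelman–Rubin statistics.

The package ships:

- `simulate` — synthetic unbalanced-panel generator (the real survey data
  are access-restricted), including planted filter-triggering respondents;
- `preprocess` — the three respondent-exclusion rules (fewer than five
  responses; all-constant outcome; residence abroad), k-NN imputation of
  missing covariates, and design-matrix construction for the four nested
  covariate specifications (Models 1–4) across marital-status × gender
  strata;
- `sampler` / `BayesianPanelLogit` — the PG-Gibbs/ASIS engine, both as
  functions and as a scikit-learn estimator (`fit(X, y, groups=...)`);
- `summary` — WAIC, split R-hat, posterior tables with 95% credible
  intervals and exclude-zero flags, ordered individual-effect tables;
- `suite` — the full (stratum × model) comparison grid;
- a `pglogit` CLI with `simulate`, `preprocess`, `fit` and `suite`
  subcommands.

## Worked example

```python
from pglogit import (SimConfig, generate_panel, apply_filters, impute_knn,
                     ModelSpec, build_design, run_gibbs, SamplerConfig, summarize)

cfg = SimConfig(
    n_respondents=150,
    true_beta={"sat_life_overall": 0.25, "spouse_yes": 0.3},
    missing_rate=0.02,
    seed=1,
)
table = generate_panel(cfg)                      # long-format survey table
filtered, report = apply_filters(table)          # exclusion conditions 1-3
completed = impute_knn(filtered, k=5)            # k-NN completion
data = build_design(completed, ModelSpec(model_id=2))   # satisfaction model
draws = run_gibbs(data, config=SamplerConfig(n_iter=4000, n_burn=1000,
                                             n_chains=2, seed=3))
s = summarize(draws)
print(s.table.loc[["beta[spouse_yes]", "beta[sat_life_overall]",
                   "mu_alpha", "sigma_alpha_sq"]].round(3))
print(f"WAIC = {s.waic:.1f}, max split R-hat = {s.max_rhat:.3f}")
```

prints

```
                         mean     sd   q2.5  q97.5  excludes_zero   rhat
beta[spouse_yes]        0.266  0.168 -0.061  0.601          False  1.000
beta[sat_life_overall]  0.221  0.039  0.146  0.298           True  1.000
mu_alpha               -0.480  0.443 -1.395  0.399          False  1.001
sigma_alpha_sq          0.581  0.165  0.308  0.955           True  1.002
WAIC = 1380.8, max split R-hat = 1.002
```

The satisfaction coefficient is recovered near its generating value 0.25
and its 95% interval excludes zero; the spouse dummy (generating value
0.3, but only 150 respondents) is positive with an interval still
spanning zero. All split R-hats sit at 1.00, i.e. the two interweaved
chains have mixed.

The same model can be fitted through the scikit-learn surface:

```python
from pglogit import BayesianPanelLogit
est = BayesianPanelLogit(n_iter=2000, n_burn=500, random_state=0)
est.fit(X, y, groups=respondent_ids)
est.beta_, est.sigma_alpha_sq_, est.summary_.waic
```

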