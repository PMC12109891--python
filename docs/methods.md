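# Methods

## Model and estimation

The observable is a binary respondent-by-wave indicator in an unbalanced
panel: respondent r contributes T_r ∈ {1..9} annual waves. The model is a
random-intercept logit,

    y_rt ~ Bernoulli(logistic(alpha_r + x_rt' beta)),
    alpha_r ~ N(mu_alpha, sigma_alpha^2),

with conjugate hyperpriors beta ~ N(mu_beta, A_beta^{-1}),
mu_alpha ~ N(mu_0, sigma_0^2), sigma_alpha^2 ~ IG(nu_0/2, lambda_0/2).
No global intercept column is included — the respondent effects absorb
the level, so adding one would be unidentified against mu_alpha.

Default priors (used for every model in a suite): mu_beta = 0,
Sigma_beta = A_beta^{-1} = 100 I, mu_0 = 0, sigma_0^2 = 100, and the
inverse-gamma shape/scale written in "reported" form as s_alpha = s_eps
= 1, i.e. nu_0 = lambda_0 = 2. The (phi_alpha, tau_alpha^2, s_alpha,
s_eps) aliases map as phi_alpha = mu_0, tau_alpha^2 = sigma_0^2,
nu_0/2 = s_alpha, lambda_0/2 = s_eps; this mapping is a package
convention (`PriorConfig.from_reported`).

### Pólya–Gamma augmentation

Writing kappa_rt = y_rt − 1/2, the identity

    e^{a psi} / (1 + e^{psi}) = ∫ 2^{-1} e^{kappa psi − omega psi²/2} p(omega) d omega,
    omega ~ PG(1, 0),

turns each Bernoulli-logit factor into a Gaussian factor conditional on
omega, with omega_rt | · ~ PG(1, psi_rt). One Gibbs sweep then draws, in
order: omega (augmentation refresh), alpha (independent univariate
normals — the conditional precision V + sigma_alpha^{-2} I is diagonal),
beta (one multivariate normal via Cholesky of X'ΩX + A_beta), mu_alpha
and sigma_alpha^2 (conjugate normal and inverse-gamma). Sufficient blocks
(per-respondent kappa sums, omega-weighted covariate sums Z, the
kappa-weighted covariate total, and the per-respondent omega totals) are
recomputed from scratch each sweep; respondent blocks are contiguous by
dataset invariant, so these are cheap `reduceat`/`bincount` reductions.

The PG(1, z) device is an exact Devroye-type alternating-series rejection
sampler (truncation point 0.64, truncated-inverse-Gaussian /
truncated-exponential proposal mixture), JIT-compiled with numba; integer
b sums b independent PG(1, z) draws. An independent truncated-series
sampler (the gamma-convolution representation cut at `series_terms`
terms, default 200, plus a gamma correction moment-matched to the
discarded tail) is kept for cross-checks and for non-integer b. The two
samplers agree in distribution (two-sample KS) and both match the closed
forms E = (b/2c) tanh(c/2) and the corresponding variance.

### ASIS interweaving

With thousands of weakly-identified intercepts, the centred Gibbs sweep
mixes slowly in (mu_alpha, sigma_alpha^2). After each sweep the sampler
therefore re-expresses the intercepts in the ancillary (non-centred)
parameterization alpha~_r = (alpha_r − mu_alpha)/sigma_alpha and redraws
the hyperparameters there, conditional on the current omega:

- mu_alpha: its ancillary conditional is Gaussian (psi is linear in
  mu_alpha given omega) and is drawn exactly;
- sigma_alpha^2: updated by random-walk Metropolis on log sigma_alpha^2
  (2 proposals per sweep, step 0.25) against the exact ancillary
  conditional — inverse-gamma prior plus Jacobian plus the
  omega-Gaussianized likelihood terms, which are linear-plus-quadratic in
  sigma_alpha. A rejected proposal leaves the sub-move unchanged, which
  is still a valid MCMC transition;

and finally maps back alpha = mu_alpha + sigma_alpha · alpha~. Both
half-updates are exact conditional draws of the augmented joint, so the
interweave preserves the posterior; tests verify ASIS-on and ASIS-off
chains agree on all posterior summaries within Monte Carlo error, and a
Geweke-style successive-conditional simulation reproduces the prior
marginals with the interweave enabled.

The update order (omega, alpha, beta, mu_alpha, sigma_alpha^2, then the
interweave) is fixed for reproducibility; chains are seeded from
independent `SeedSequence` substreams of a single seed, and identical
inputs yield bit-identical draw stores. Initialization is neutral:
alpha = 0, beta = 0, mu_alpha = 0, sigma_alpha^2 = 1, omega refreshed
first.

### Diagnostics and model comparison

WAIC is computed on the deviance scale, waic = −2(lppd − p_waic), from
the stored pointwise log-likelihood matrix, with a stable log-mean-exp
for lppd and the sample-variance form for p_waic. The pointwise terms
condition on the sampled intercepts (conditional WAIC), matching the
per-observation factorization of the likelihood; this is the standard
choice for random-effect logit draws that store alpha. Convergence uses
the split-half Gelman–Rubin statistic (each chain halved, so R chains
yield 2R sequences); a zero within-sequence variance is reported as NaN
("degenerate") rather than an error. Credible intervals are central
(equal-tailed); a coefficient is flagged significant when its 95%
interval excludes zero. Individual effects are reported as a
rank-ordered table of posterior means with ±1 posterior-SD bands.

## Respondent filters, imputation, design

Respondents are excluded when they (1) contribute fewer than five waves,
(2) have an all-constant outcome sequence — such respondents carry no
information about their own intercept, making estimation impossible for
them — or (3) reside outside the home country in any wave. A respondent
may trip several conditions; the report tallies each condition separately
but removes the respondent once. Filtering precedes imputation because
all three conditions depend only on always-observed fields; rows destined
for removal are never imputed.

Missing covariate cells are completed by a deterministic k-NN rule
(default k = 5): standardized Euclidean distance over the chosen distance
columns (all covariates by default), restricted to the coordinates
observed in the query row, with categorical mismatches contributing a
squared distance of 2 (one-hot geometry); quantitative cells take the
neighbour mean, categorical cells the neighbour mode with ties broken
toward the nearest tied neighbour; equidistant neighbours order by row
index. The column set, k, and standardization are package choices — the
property tests (oracle equality, convexity, observed-cell preservation)
are k-agnostic.

The design builder codes each dummy block 0/1 against its reference level
(year 2014, age under 40, Kanto, government-designated major city, no
spouse, female), passes satisfaction items through on the centred scale,
and assumes monetary amounts are already log(1 + raw) (a `raw_money` flag
applies the transform instead). Four nested specifications are supported:
Model 1 all blocks (52 columns pooled), Model 2 controls + satisfaction
(30), Model 3 controls + finance (45), Model 4 controls only (23); the
spouse and sex dummies enter only the pooled stratum, and the
spouse-income items are dropped in unmarried strata where they are
structurally zero. Stratum membership for marital status, which can
change across waves, is the modal spouse status (ties count as married) —
respondent-level stratification is required because the intercepts are
respondent-level. With R respondents the sampler estimates R + K + 2
parameters (omega latents are augmentation variables, not parameters);
Model 1 with R = 2280 gives 2334.

## Synthetic-data generator

The generator emulates the structural features the analysis relies on,
not any real survey's joint distribution:

- unbalanced contiguous participation, T_r uniform on {5..9} by default
  (the post-filter regime);
- intercepts alpha_r iid N(mu_alpha, sigma_alpha^2), recorded in a truth
  sidecar together with each respondent's planted role;
- dummy blocks drawn categorically with level probabilities shaped like
  the survey's published marginals (sex and region fixed per respondent,
  the rest per wave); satisfaction items as clipped, rounded Gaussians on
  {−5..5}; monetary items as log1p of zero-inflated log-normals (so the
  marginals are bounded below by zero and zero-inflated). Only these
  marginal shapes are claimed — no joint or temporal covariate structure;
- planted degenerate respondents for filter testing: all-one and all-zero
  responders, short participants (2–4 waves, at least two so the short
  and constant-outcome conditions stay disjoint), and foreign residents
  (one wave abroad); roles are disjoint by construction;
- item-level missingness applied to covariate cells only, never to
  outcome, identifiers, year or residence;
- one global seed expanded into per-purpose substreams (roles,
  participation, effects, covariates, outcomes, missingness), so changing
  one stage leaves the others untouched.

By default (`ensure_nonconstant=True`) non-planted respondents' outcome
vectors are redrawn until non-constant, so a generated table passes the
filters with exactly its planted respondents removed. This conditioning
tilts outcome sequences of extreme-intercept respondents; tests that
assert the unconditional Bernoulli law switch it off.

What passing tests on these data do not show: robustness to covariate
dependence, temporal persistence, informative missingness, or panel
attrition correlated with the outcome — none of which the generator
produces.

## Problem sizes and numerical choices

Simulation studies in the test-suite run at deliberately reduced scale:
the convergence study uses R = 200, K = 10, 4 × 6000 sweeps; parameter
recovery 20 replications at R = 300 with single 2000-sweep chains; model
selection 20 replications at R = 80 with 600-sweep chains over all four
specifications; the quadrature comparison a 3-respondent fixture with a
161 × 81 × 61 (beta, mu_alpha, sigma_alpha^2) grid and a 321-point
intercept grid. Logistic and log(1+e^psi) evaluations use branch-safe
forms exact for all finite psi. The beta update factorizes the precision
with a Cholesky; a non-positive-definite precision (possible only with a
degenerate design and a vanishing prior) raises with advice to
strengthen A_beta. Suite cells derive their chain seeds from the global
seed and the cell label via SHA-256, so a grid run is reproducible
bit-for-bit and cells are insensitive to grid order.

## Known limitations

- **sigma_alpha^2 is attenuated by the constant-outcome exclusion.** With
  at most nine binary observations per respondent, respondents with
  extreme intercepts are the likeliest to respond identically in every
  wave. Removing them (filter condition 2 — estimation is impossible for
  them) both truncates the retained intercept distribution and tilts the
  retained extreme respondents' sequences toward mixed outcomes. On
  simulated panels with T_r ∈ {5..9} and sigma_alpha = 1, the posterior
  mean of sigma_alpha^2 after filtering centres near 0.6 even though the
  sampler is exact (it matches deterministic quadrature on small fixtures,
  and recovers sigma_alpha^2 ≈ 1 when constant responders are retained in
  a diagnostic fit). Estimates of the intercept variance from filtered
  panel data should therefore be read as the heterogeneity of the
  estimable sub-population, not of the full population. Slope coverage is
  unaffected: 95% intervals cover the generating betas at their nominal
  rate in the recovery study.
- Conditional (not marginal) WAIC: comparisons are of one-step-ahead fit
  given the intercepts; models differing mainly in the hierarchy would
  need the marginal version, which the package does not compute.
- The k-NN imputation is single imputation; imputation uncertainty is not
  propagated into the posterior.
- The exact PG device requires integer b (the model only ever needs
  b = 1); non-integer b falls back to the truncated-series sampler.
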