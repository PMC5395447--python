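# Methods

## The scientific problem

When two closely related species replace each other along an elevation or
climate gradient, the turnover can reflect divergent environmental
requirements, direct interaction (e.g. interspecific territoriality), or
both.  `parapatry` implements the two complementary lines of inference used
to tease these apart in songbird systems: (i) a joint species distribution
model (JSDM) that splits pairwise co-occurrence into an *environmental*
component (correlated responses to measured covariates) and a *residual*
component (association left over, potentially biotic), and (ii) a
statistical battery for song-playback territorial-intrusion experiments,
including a power analysis in which the expected heterospecific response is
scaled by the observed spatial segregation of the pair.

## The joint model

For site `i` and species `j` with covariate row `x_i`:

    z_ij = x_i' beta_j + e_ij,   e_i ~ N(0, R),   y_ij = 1{z_ij > 0}

`R` is a correlation matrix; its off-diagonals are the residual
correlations.  The environmental correlation of a pair is the Pearson
correlation across sites of the linear predictors `x' beta_j` and
`x' beta_k`, computed per posterior draw.  Intervals are equal-tailed
2.5–97.5% quantiles; an effect is "significant" when its 95% interval
excludes zero; point estimates are posterior means.

### Sampler

A bespoke Gibbs sampler with truncated-normal data augmentation:

* `z` — for each species, the conditional distribution given the other
  species' latents under `N(B x, R)` is univariate normal truncated at 0;
  draws use the inverse-CDF (`ndtr`/`ndtri`) with probabilities clipped to
  `[1e-12, 1 - 1e-12]` against tail underflow.
* `beta` — conjugate multivariate-normal update of the stacked coefficient
  vector with precision `kron(R^-1, X'X) + tau I`, under independent
  `N(0, 1/tau)` priors (default `tau = 0.001`, i.e. essentially flat on the
  probit scale).
* `R` — an unrestricted covariance is drawn from its inverse-Wishart
  conditional (prior: identity scale, `J + 1` degrees of freedom) and
  rescaled to a correlation matrix; the latents and coefficients are
  rescaled by the same standard deviations, keeping the chain on the
  identified correlation scale (parameter-expanded marginal augmentation).
  The inverse-Wishart prior is a package design choice: it is the standard
  JSDM identification strategy, works for any number of species, and its
  weight (~`J + 1` pseudo-observations) is negligible at survey sample
  sizes.  `fit_jsdm(..., fix_residual=True)` pins `R` at the identity,
  collapsing the model to independent probit regressions (used for the
  maximum-likelihood cross-check).

Initialisation: `beta = 0`, `z = ±0.5` according to `y`, `R = I`.  Chains
get independent streams spawned from the master seed, so fits are exactly
reproducible.  Default schedule: 3 chains × 6,000 iterations, 3,000
burn-in, thinning 3 (1,000 draws per chain).  This desk-scale schedule
mixes well for 2-species models at n ≈ 1,500 (split-chain R-hat < 1.05 in
the test suite); field-scale schedules of 150,000+ iterations remain
available through `McmcConfig`.  Convergence is quantified with the
split-chain Gelman–Rubin statistic (constant chains report 1 by
convention).

### Prediction and cross-validation

Held-out sites are scored with the posterior mean of `Phi(x' beta_j)` — the
residual term is unobservable for a new site, and per-species
discrimination (AUC) only needs the marginal probability.  Predictors are
centered and scaled by the *training* mean and standard deviation (n−1
denominator); quadratic terms square the standardised linear column and are
then standardised again, with both passes' statistics stored for reuse, so
no information leaks from held-out rows.  Candidate models are compared by
stratified K-fold AUC (rank-based, ties counting ½): folds stratify on the
joint presence/absence pattern across species, dealt cyclically so fold
sizes differ by at most one site and each species' presences per fold stay
within one of perfect proportionality (a seeded search over dealing orders
plus a local swap repair enforces this).  The best model maximises the
unweighted species-average of mean AUC, with ties broken by parsimony and
then name.

## Checkerboard score

Pairwise segregation is `C = (r1 - S)(r2 - S) / (r1 r2)` from the occupied
site counts `r1, r2` and shared count `S`: 0 under complete sympatry, 1
under complete segregation.  The unnormalised checkerboard-unit count
`(r1 - S)(r2 - S)` is recoverable from the stored counts.  Sites holding
neither species do not affect the score, so the same code applies at any
grain (survey plot or atlas cell).

## Playback battery

* **Response validation** — paired sign test (pre-playback vs playback
  distance), zeros dropped, continuity-corrected normal `z` plus the exact
  binomial p-value.
* **Confound check** — OLS of each response on month, hour and their
  product (numeric covariates), reporting per-term p-values.
* **Approach distance** — Box-Cox transform (profile-MLE of λ by bounded
  search on [−2, 2], tolerance 1e-5), then one-way ANOVA with Tukey HSD
  contrasts via the studentized-range distribution.  If all observations
  are identical, F = 0 and all p = 1 by convention.
* **Latency** — Kruskal–Wallis with tie correction, Dunn pairwise z tests
  on mean ranks with tie-corrected variance; pairwise p-values unadjusted
  by default (Bonferroni/Holm optional).
* **Effect size and power** — Cohen's d with the pooled standard
  deviation; power of a two-sided two-sample t test at the
  segregation-scaled effect `d × C`, using the noncentral-t distribution
  with noncentrality `d C sqrt(n1 n2 / (n1 + n2))`.  At a null effect the
  power equals α exactly; power ≥ 0.80 counts as adequate.  The scaling
  logic: a fully segregated pair (C = 1) is expected to defend against a
  congener as strongly as against a conspecific; a fully sympatric pair
  (C = 0) not at all.

## Synthetic data

The generator emulates a temperate-mountain survey: plot elevations uniform
on 120–2,620 m; mean annual temperature linear in elevation (default lapse
−4.7 °C/km from a 14.2 °C sea-level intercept, reproducing a 1.9–13.6 °C
envelope) plus Gaussian noise (s.d. 0.8 °C); rainfall increasing with
elevation (≈ 480–2,100 mm); slope, solar radiation and roughness as
independent terrain covariates; six microhabitat covers drawn from an
elevation-modulated Dirichlet (forest weight collapses above a ~1,400 m
treeline, rock/bare ground grow with elevation) so compositions sum to one
by construction; heterogeneity is the Simpson index `1 − Σ p²` of the
covers (maximum `1 − 1/k` for `k` categories; the unnormalised form is
used deliberately).  Occurrences are drawn from the same latent probit
model the fitting code assumes, with user-supplied true coefficients and
residual correlation.  Playback responses are lognormal by default
(strictly positive, right-skewed — the reason field data need Box-Cox),
mean-parameterised per treatment group, with a common pre-playback
distance.

What the generator does **not** emulate: spatial autocorrelation, detection
error, observer effects, unmeasured-covariate confounding, and
non-Gaussian residual dependence.  Passing recovery tests therefore show
the estimator is correct under its own assumptions, not that those
assumptions hold for any particular field system — in real data a negative
residual correlation can still reflect a missing covariate rather than
competition.

## Test problem sizes

Recovery and calibration checks use n = 1,500 sites, 2 species, 3
predictors + intercept, true residual correlation −0.5 (or 0), the default
3 × 6,000 schedule, and 5 seeded replicates per property in the default
suite (a 20-replicate profile is the nightly schedule; thresholds scale
proportionally: ≥ 4/5 interval coverage and accuracy, ≤ 1/5 null flags).
Recovery surfaces use elevation, slope and solar radiation as predictors:
the generator's climate covariates are near-collinear with elevation by
construction (r ≈ −0.97), and with collinear columns individual probit
coefficients are not identifiable to ±0.2 at this n — a collinearity
property, not a sampler defect.  Cross-validation sanity runs 20 replicates
at n = 300 with a reduced schedule.  `scripts/acceptance.py` re-runs the
same computations at 6 replicates.

## Numerical conventions and edge cases

* Sample standard deviations use the n−1 denominator everywhere.
* Presence uses the strict inequality `z > 0`; ties have probability zero.
* Forest filtering keeps plots with cover strictly below the threshold.
* An all-present or all-absent species is a fit error (degenerate probit);
  a species absent everywhere makes the C-score a computation error.
* AUC requires both classes; identical scores give exactly 0.5.
* Quantiles are linear-interpolation (NumPy default); "significant" means
  the equal-tailed 95% interval excludes 0.
* Far-tail noncentral-t evaluations that underflow are treated as zero
  mass.

## Known limitations

Two species are the intended use case; the sampler and stratification
generalise to more, but fold construction enumerates joint patterns
(2^J strata) and the swap repair is heuristic for large J.  No spatial
random effects, phylogenetic priors, interaction terms, or missing-data
handling.  Dunn and sign tests use normal approximations (exact binomial
p-value reported alongside the sign z).  The model-selection rule assumes
AUC is the relevant currency; no information criteria are computed.
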