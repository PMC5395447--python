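# parapatry

Statistical tools for asking why two closely related species partition a
landscape: shared or divergent environmental responses, or interaction?
Written for ecologists analysing paired presence/absence surveys along
environmental gradients together with song-playback (simulated
territorial-intrusion) experiments in the contact zone.

## What it computes

**Joint species distribution model (JSDM).** A Bayesian multivariate-probit
regression fitted by a Gibbs sampler with latent-variable augmentation: for
site *i* and species *j*,

```
z_ij = x_i' β_j + e_ij,   e_i ~ N(0, R),   y_ij = 1{z_ij > 0}
```

with vague N(0, 1000) priors on the coefficients and an inverse-Wishart
prior on the (rescaled) residual covariance.  The posterior separates two
pairwise quantities:

* **environmental correlation** — correlation across sites of the species'
  linear predictors x'β_j and x'β_k (similar vs. diverging responses to
  the measured environment);
* **residual correlation** — the off-diagonal of R: co-occurrence (+) or
  exclusion (−) left unexplained by the environment, potentially biotic.

An effect is significant when its equal-tailed 95% credible interval
excludes zero.  Candidate predictor sets are compared by stratified K-fold
cross-validation with per-species rank-based AUC.

**Checkerboard score.** Pairwise segregation
C = (r₁−S)(r₂−S)/(r₁r₂) ∈ [0, 1] from occupied-site counts r₁, r₂ and
shared count S (0 = complete sympatry, 1 = complete segregation).

**Playback battery.** Sign test (pre- vs during-playback approach),
temporal-confound linear models, Box-Cox + one-way ANOVA + Tukey HSD for
approach distance, Kruskal–Wallis + Dunn for latency, Cohen's d, and the
power of the congener-vs-control contrast at the segregation-scaled effect
size d·C (noncentral-t, two-sided; power ≥ 0.80 deemed adequate).

**Synthetic data.** An elevation-gradient survey generator (climate via a
lapse rate, Dirichlet microhabitat compositions, Simpson heterogeneity)
and a playback-trial generator, both with known ground truth — every
estimator ships with a parameter-recovery test surface.

## Worked example

```python
import numpy as np
from parapatry import *

sites = generate_sites(GradientConfig(n_sites=1000, seed=42))
spec = ModelSpec("gradient", ["elevation", "slope", "solar_radiation"],
                 ["tree_pipit", "water_pipit"])
beta = np.array([[ 0.2, -1.0,  0.3, 0.0],    # declines with elevation
                 [-0.4,  1.1, -0.2, 0.1]])   # replaces it upslope
truth = JsdmTrueParams(beta, np.array([[1.0, -0.5], [-0.5, 1.0]]))
occ = generate_occurrences(sites, spec, truth, seed=7)
sites, occ = filter_by_forest_cover(sites, occ, 0.8)

post = fit_jsdm(build_design_matrix(sites, spec), occ, McmcConfig(seed=1))
env = environmental_correlation(post, ("tree_pipit", "water_pipit"))
res = residual_correlation(post, ("tree_pipit", "water_pipit"))
cs = c_score(occ, "tree_pipit", "water_pipit")

trials = generate_playback_trials(PlaybackGenConfig(n_per_group=25, seed=3))
bc = boxcox_mle(trials["min_distance_m"].to_numpy())
contrast = anova_tukey(trials.assign(d=bc.transformed), "d")
eff = cohens_d(trials.loc[trials.treatment == "conspecific", "min_distance_m"],
               trials.loc[trials.treatment == "control", "min_distance_m"])
pw = segregation_scaled_power(abs(eff.d), cs.c_score, 25, 25)
```

Output:

```
environmental corr: -0.99 [-1.00, -0.98] significant=True
residual corr:      -0.45 [-0.55, -0.33] significant=True
C-score: 0.70 (r1=556, r2=374, shared=74)
Box-Cox lambda: 0.30; ANOVA F = 61.3, p = 2.9e-16
d (conspecific vs control) = -2.47; scaled d = 1.72; power = 1.00
```

Reading: the two synthetic species respond in opposite ways to the
gradient (environmental correlation ≈ −1) *and* exclude each other beyond
that (residual correlation −0.45, interval excluding 0 — recovering the
true −0.5), producing strong spatial segregation (C = 0.70).  The playback
trials show a much closer approach to conspecific song than to the control
(ANOVA on Box-Cox-transformed distances, |d| = 2.47), and at the
segregation-scaled effect size 2.47 × 0.70 the design has essentially full
power to detect a heterospecific response if one existed.

A full run (data → forest filter → CV model selection → fit →
correlations → C-scores → playback → JSON report) is driven by one config
file:

```
parapatry run --config config.yaml --outdir results/
```

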