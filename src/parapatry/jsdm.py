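"""Joint species distribution model: multivariate-probit regression by Gibbs sampling.

The model couples one probit regression per species through a latent Gaussian
residual.  For site ``i`` with covariate row ``x_i`` and species ``j``:

    z_ij = x_i' beta_j + e_ij,        e_i ~ N(0, R)
    y_ij = 1  iff  z_ij > 0

where ``R`` is a correlation matrix (unit diagonal).  Off-diagonal entries of
``R`` are the *residual* correlations: association between species occurrences
left over once the measured environment is accounted for.  The *environmental*
correlation of a species pair is the correlation, across sites, of their
linear predictors ``x'beta_j`` and ``x'beta_k`` — similarity of the two
species' fitted responses to the environment.

Sampling uses truncated-normal data augmentation for ``z``, a conjugate
normal update for the coefficients under vague N(0, 1/prior_precision)
priors, and an inverse-Wishart draw for the latent residual covariance which
is rescaled to a correlation matrix each sweep (the latent variables and
coefficients are rescaled with it, keeping the chain on the identified
correlation scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

from .errors import ComputationError, DiagnosticError, FitError, ValidationError

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "McmcConfig",
    "JsdmPosterior",
    "CorrelationEstimate",
    "ParamSummary",
    "build_design_matrix",
    "fit_jsdm",
    "environmental_correlation",
    "residual_correlation",
    "predict_marginal",
    "rhat",
    "posterior_summary",
    "correlation_table",
]

_TINY = 1e-12


# ---------------------------------------------------------------------------
# Model specification and design matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which predictors (and which quadratic terms) enter the shared design.

    Parameters
    ----------
    name
        Label used in cross-validation reports.
    predictors
        Column names of the site table entering as linear terms.  May be
        empty for an intercept-only model.
    quadratic
        Subset of ``predictors`` that additionally enter squared.
    species
        Names of the modelled species (columns of the occurrence matrix).
    """

    name: str
    predictors: tuple[str, ...]
    species: tuple[str, ...]
    quadratic: tuple[str, ...] = ()

    def __init__(self, name: str, predictors: Sequence[str],
                 species: Sequence[str], quadratic: Sequence[str] = ()):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "predictors", tuple(predictors))
        object.__setattr__(self, "species", tuple(species))
        object.__setattr__(self, "quadratic", tuple(quadratic))
        unknown = set(self.quadratic) - set(self.predictors)
        if unknown:
            raise ValidationError(
                f"quadratic terms not among predictors: {sorted(unknown)}")
        if len(self.species) < 2:
            raise ValidationError("a joint model needs at least 2 species")
        if len(set(self.predictors)) != len(self.predictors):
            raise ValidationError("duplicate predictor names")

    @property
    def n_params(self) -> int:
        """Number of design columns including the intercept."""
        return 1 + len(self.predictors) + len(self.quadratic)


@dataclass
class DesignMatrix:
    """Centered/scaled design with the transform parameters kept for reuse.

    The first column is the intercept; every other column has sample mean 0
    and sample standard deviation 1 (n-1 denominator).  Quadratic columns are
    built by squaring the already-standardised linear column and then
    standardising the square itself; ``quad_center``/``quad_scale`` record
    that second pass so held-out data can be transformed with training
    statistics only.
    """

    values: np.ndarray
    columns: list[str]
    site_ids: np.ndarray
    spec: ModelSpec
    lin_center: dict[str, float]
    lin_scale: dict[str, float]
    quad_center: dict[str, float] = field(default_factory=dict)
    quad_scale: dict[str, float] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    def transform(self, sites: pd.DataFrame) -> np.ndarray:
        """Apply the stored centering/scaling to new sites."""
        missing = [p for p in self.spec.predictors if p not in sites.columns]
        if missing:
            raise ValidationError(f"new sites lack predictors: {missing}")
        n = len(sites)
        cols = [np.ones(n)]
        std_lin = {}
        for p in self.spec.predictors:
            v = (sites[p].to_numpy(float) - self.lin_center[p]) / self.lin_scale[p]
            std_lin[p] = v
            cols.append(v)
        for p in self.spec.quadratic:
            q = std_lin[p] ** 2
            cols.append((q - self.quad_center[p]) / self.quad_scale[p])
        return np.column_stack(cols)


def build_design_matrix(sites: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Build the standardised design matrix for ``spec`` from a site table.

    Raises
    ------
    ValidationError
        If a predictor is missing, contains missing values, or has zero
        variance (naming the offending column).
    """
    missing = [p for p in spec.predictors if p not in sites.columns]
    if missing:
        raise ValidationError(f"predictors not in site table: {missing}")
    n = len(sites)
    if n < 2:
        raise ValidationError("need at least 2 sites to scale predictors")
    columns = ["intercept"]
    cols = [np.ones(n)]
    lin_center, lin_scale = {}, {}
    std_lin = {}
    for p in spec.predictors:
        raw = sites[p].to_numpy(float)
        if np.isnan(raw).any():
            raise ValidationError(f"missing values in predictor {p!r}")
        c = raw.mean()
        s = raw.std(ddof=1)
        if s < _TINY:
            raise ValidationError(f"zero-variance predictor {p!r}")
        lin_center[p], lin_scale[p] = float(c), float(s)
        v = (raw - c) / s
        std_lin[p] = v
        cols.append(v)
        columns.append(p)
    quad_center, quad_scale = {}, {}
    for p in spec.quadratic:
        q = std_lin[p] ** 2
        c = q.mean()
        s = q.std(ddof=1)
        if s < _TINY:
            raise ValidationError(f"zero-variance quadratic term {p!r}^2")
        quad_center[p], quad_scale[p] = float(c), float(s)
        cols.append((q - c) / s)
        columns.append(f"{p}^2")
    site_ids = (sites["site_id"].to_numpy() if "site_id" in sites.columns
                else sites.index.to_numpy())
    return DesignMatrix(np.column_stack(cols), columns, site_ids, spec,
                        lin_center, lin_scale, quad_center, quad_scale)


# ---------------------------------------------------------------------------
# MCMC configuration and posterior container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McmcConfig:
    """Chain schedule and prior settings for the Gibbs sampler.

    ``prior_precision`` is the precision of the independent zero-mean normal
    priors on every regression coefficient (default 0.001, i.e. a vague
    N(0, 1000) prior on the probit scale).
    """

    n_chains: int = 3
    n_iter: int = 6_000
    n_burnin: int = 3_000
    thin: int = 3
    seed: int = 0
    prior_precision: float = 0.001

    def __post_init__(self):
        if self.n_burnin >= self.n_iter:
            raise ValidationError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValidationError("need >= 2 chains for convergence diagnostics")
        if self.prior_precision <= 0:
            raise ValidationError("prior_precision must be > 0")

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


@dataclass
class JsdmPosterior:
    """Posterior draws of the joint model.

    Attributes
    ----------
    beta
        Array of shape (draws, species, design columns), probit scale.
    rho
        Residual correlation draws, shape (draws, species, species); every
        slice is symmetric with unit diagonal.
    chain
        Chain label per draw.
    """

    beta: np.ndarray
    rho: np.ndarray
    chain: np.ndarray
    spec: ModelSpec
    design: DesignMatrix

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def species(self) -> tuple[str, ...]:
        return self.spec.species

    def species_index(self, name: str) -> int:
        try:
            return self.spec.species.index(name)
        except ValueError:
            raise ValidationError(f"unknown species {name!r}") from None


@dataclass(frozen=True)
class CorrelationEstimate:
    """Posterior summary of one pairwise correlation.

    ``significant`` is True iff the equal-tailed 95% credible interval
    excludes zero.
    """

    kind: str  # "environmental" | "residual"
    species_a: str
    species_b: str
    mean: float
    lower: float
    upper: float
    significant: bool

    def __post_init__(self):
        tol = 1e-9  # rounding slack: the mean of identical draws can differ
        if not (self.lower - tol <= self.mean <= self.upper + tol):
            raise ValidationError("quantile ordering violated")


@dataclass(frozen=True)
class ParamSummary:
    name: str
    mean: float
    lower: float
    upper: float
    rhat: float


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _as_occurrence_array(design: DesignMatrix, occ: pd.DataFrame) -> np.ndarray:
    species = list(design.spec.species)
    missing = [s for s in species if s not in occ.columns]
    if missing:
        raise ValidationError(f"occurrence matrix lacks species: {missing}")
    if len(occ) != design.n_sites:
        raise ValidationError(
            f"occurrence rows ({len(occ)}) do not align with design rows "
            f"({design.n_sites})")
    occ_ids = (occ["site_id"].to_numpy() if "site_id" in occ.columns
               else occ.index.to_numpy())
    if not np.array_equal(np.asarray(occ_ids), np.asarray(design.site_ids)):
        raise ValidationError("site ids of occurrence matrix and design differ")
    y = occ[species].to_numpy()
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("occurrence entries must be 0/1")
    for k, s in enumerate(species):
        tot = int(y[:, k].sum())
        if tot == 0 or tot == len(y):
            raise FitError(
                f"species {s!r} is {'always present' if tot else 'never observed'}; "
                "the probit regression is degenerate")
    return y.astype(float)


def _sample_truncnorm(mean: np.ndarray, sd: float, positive: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw of N(mean, sd^2) truncated to (0, inf) or (-inf, 0]."""
    a = ndtr(-mean / sd)  # P(z <= 0)
    u = rng.random(mean.shape[0])
    p = np.where(positive, a + u * (1.0 - a), u * a)
    p = np.clip(p, _TINY, 1.0 - _TINY)
    return mean + sd * ndtri(p)


def _run_chain(X: np.ndarray, y: np.ndarray, mcmc: McmcConfig,
               rng: np.random.Generator, fix_residual: bool
               ) -> tuple[np.ndarray, np.ndarray]:
    n, p = X.shape
    J = y.shape[1]
    positive = y > 0.5
    XtX = X.T @ X
    tau = mcmc.prior_precision
    eye_jp = np.eye(J * p)

    B = np.zeros((J, p))
    R = np.eye(J)
    z = np.where(positive, 0.5, -0.5)

    n_keep = mcmc.n_draws_per_chain
    beta_out = np.empty((n_keep, J, p))
    rho_out = np.empty((n_keep, J, J))
    keep = 0

    iw_df = n + J + 1  # prior df J+1 plus n observations

    for t in range(mcmc.n_iter):
        # --- latent z: species-wise conditional truncated normals
        mu = X @ B.T
        for j in range(J):
            others = [k for k in range(J) if k != j]
            if others:
                Roo = R[np.ix_(others, others)]
                w = np.linalg.solve(Roo, R[others, j])
                cond_var = R[j, j] - R[j, others] @ w
                cond_mu = mu[:, j] + (z[:, others] - mu[:, others]) @ w
            else:
                cond_var = R[j, j]
                cond_mu = mu[:, j]
            sd = float(np.sqrt(max(cond_var, _TINY)))
            z[:, j] = _sample_truncnorm(cond_mu, sd, positive[:, j], rng)

        # --- coefficients: conjugate normal update of vec(B) (row-major)
        W = np.linalg.inv(R)
        prec = np.kron(W, XtX) + tau * eye_jp
        rhs = (W @ z.T @ X).ravel()
        L = np.linalg.cholesky(prec)
        mean_b = cho_solve((L, True), rhs)
        # draw: mean + L^{-T} eps with prec = L L'
        eps = rng.standard_normal(J * p)
        b = mean_b + solve_triangular(L.T, eps, lower=False)
        B = b.reshape(J, p)

        # --- residual covariance -> correlation (with latent rescaling)
        if not fix_residual:
            E = z - X @ B.T
            scale = np.eye(J) + E.T @ E
            Sigma = invwishart.rvs(df=iw_df, scale=scale, random_state=rng)
            Sigma = np.atleast_2d(Sigma)
            d = np.sqrt(np.diag(Sigma))
            R = Sigma / np.outer(d, d)
            R = (R + R.T) / 2.0
            np.fill_diagonal(R, 1.0)
            z = z / d
            B = B / d[:, None]

        if t >= mcmc.n_burnin and (t - mcmc.n_burnin) % mcmc.thin == 0:
            if keep < n_keep:
                beta_out[keep] = B
                rho_out[keep] = R
                keep += 1

    return beta_out[:keep], rho_out[:keep]


def fit_jsdm(design: DesignMatrix, occ: pd.DataFrame, mcmc: McmcConfig,
             fix_residual: bool = False) -> JsdmPosterior:
    """Fit the multivariate-probit joint model by Gibbs sampling.

    Parameters
    ----------
    design
        Output of :func:`build_design_matrix`; rows must align with ``occ``.
    occ
        Site-by-species 0/1 matrix containing every species in the spec.
    mcmc
        Chain schedule, seed and coefficient prior precision.
    fix_residual
        If True the residual correlation matrix is held at the identity
        (independent probit regressions); used for the single-species
        limiting case and for diagnostics.

    Returns
    -------
    JsdmPosterior
        Thinned post-burn-in draws from all chains, stacked.
    """
    y = _as_occurrence_array(design, occ)
    X = design.values
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    betas, rhos, chains = [], [], []
    for c, ss in enumerate(seeds):
        rng = np.random.Generator(np.random.PCG64(ss))
        b, r = _run_chain(X, y, mcmc, rng, fix_residual)
        betas.append(b)
        rhos.append(r)
        chains.append(np.full(len(b), c))
    return JsdmPosterior(
        beta=np.concatenate(betas),
        rho=np.concatenate(rhos),
        chain=np.concatenate(chains),
        spec=design.spec,
        design=design,
    )


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def _ci_estimate(kind: str, a: str, b: str, draws: np.ndarray) -> CorrelationEstimate:
    lo, hi = np.quantile(draws, [0.025, 0.975])
    m = float(draws.mean())
    return CorrelationEstimate(kind, a, b, m, float(lo), float(hi),
                               significant=bool(lo > 0 or hi < 0))


def environmental_correlation(post: JsdmPosterior,
                              pair: tuple[str, str]) -> CorrelationEstimate:
    """Correlation across sites of the two species' linear predictors.

    Computed per posterior draw (Pearson correlation of ``X beta_j`` and
    ``X beta_k`` over the training sites) then summarised by the posterior
    mean and equal-tailed 95% interval.  Positive values mean the species
    respond similarly to the measured environment.
    """
    ja, jb = (post.species_index(s) for s in pair)
    X = post.design.values
    if X.shape[0] < 3:
        raise ComputationError("need at least 3 sites for a correlation")
    eta_a = post.beta[:, ja, :] @ X.T  # draws x sites
    eta_b = post.beta[:, jb, :] @ X.T
    ca = eta_a - eta_a.mean(axis=1, keepdims=True)
    cb = eta_b - eta_b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ca ** 2).sum(axis=1) * (cb ** 2).sum(axis=1))
    draws = np.where(denom > _TINY, (ca * cb).sum(axis=1) / np.maximum(denom, _TINY), 0.0)
    draws = np.clip(draws, -1.0, 1.0)
    return _ci_estimate("environmental", pair[0], pair[1], draws)


def residual_correlation(post: JsdmPosterior,
                         pair: tuple[str, str]) -> CorrelationEstimate:
    """Posterior summary of the stored residual correlation for a pair."""
    ja, jb = (post.species_index(s) for s in pair)
    draws = post.rho[:, ja, jb]
    return _ci_estimate("residual", pair[0], pair[1], draws)


def predict_marginal(post: JsdmPosterior, new_sites: pd.DataFrame) -> pd.DataFrame:
    """Posterior-mean marginal presence probability Phi(x'beta) per species.

    New sites are standardised with the *training* centering/scaling, and the
    residual correlation is ignored: it is unobservable for a new site, and
    per-species discrimination only needs the marginal probability.
    """
    Xnew = post.design.transform(new_sites)
    probs = ndtr(np.einsum("djp,np->djn", post.beta, Xnew)).mean(axis=0)
    index = (new_sites["site_id"].to_numpy() if "site_id" in new_sites.columns
             else new_sites.index)
    return pd.DataFrame(probs.T, index=index, columns=list(post.species))


def _split_rhat(draws_by_chain: list[np.ndarray]) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor."""
    halves = []
    for d in draws_by_chain:
        h = len(d) // 2
        halves.extend([d[:h], d[h:2 * h]])
    L = min(len(h) for h in halves)
    if L < 2:
        raise DiagnosticError("need >= 4 draws per chain for split R-hat")
    arr = np.stack([h[:L] for h in halves])  # m x L
    within = arr.var(axis=1, ddof=1).mean()
    between = L * arr.mean(axis=1).var(ddof=1)
    if within < _TINY:
        return 1.0  # constant chains: converged by convention
    var_plus = (L - 1) / L * within + between / L
    return float(np.sqrt(var_plus / within))


def rhat(post: JsdmPosterior) -> list[ParamSummary]:
    """Posterior mean, 95% interval and split R-hat for every scalar parameter.

    Covers every regression coefficient and each off-diagonal residual
    correlation.
    """
    chains = np.unique(post.chain)
    if len(chains) < 2:
        raise DiagnosticError("R-hat needs >= 2 chains")
    J = len(post.species)
    out = []

    def summarise(name: str, flat: np.ndarray):
        per_chain = [flat[post.chain == c] for c in chains]
        r = _split_rhat(per_chain)
        lo, hi = np.quantile(flat, [0.025, 0.975])
        out.append(ParamSummary(name, float(flat.mean()), float(lo), float(hi), r))

    for j, sp in enumerate(post.species):
        for c, col in enumerate(post.design.columns):
            summarise(f"beta[{sp},{col}]", post.beta[:, j, c])
    for ja in range(J):
        for jb in range(ja + 1, J):
            summarise(f"rho[{post.species[ja]},{post.species[jb]}]",
                      post.rho[:, ja, jb])
    return out


def posterior_summary(post: JsdmPosterior) -> pd.DataFrame:
    """All parameter summaries as a tidy table (parameter, mean, q2.5, q97.5, rhat)."""
    rows = [(s.name, s.mean, s.lower, s.upper, s.rhat) for s in rhat(post)]
    return pd.DataFrame(rows, columns=["parameter", "mean", "q2.5", "q97.5", "rhat"])


def correlation_table(post: JsdmPosterior) -> pd.DataFrame:
    """Environmental and residual correlation estimates for every species pair."""
    rows = []
    sp = post.species
    for a in range(len(sp)):
        for b in range(a + 1, len(sp)):
            for est in (environmental_correlation(post, (sp[a], sp[b])),
                        residual_correlation(post, (sp[a], sp[b]))):
                rows.append((est.kind, est.species_a, est.species_b,
                             est.mean, est.lower, est.upper, est.significant))
    return pd.DataFrame(rows, columns=["kind", "species_a", "species_b",
                                       "mean", "q2.5", "q97.5", "significant"])
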