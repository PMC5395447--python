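"""Synthetic survey and playback data with known ground truth.

Every downstream stage (model fitting, cross-validation, segregation scores,
playback contrasts) is exercised against data generated here, so that
parameter-recovery and calibration tests have an exact truth to compare
against.  The generator emulates a temperate mountain survey: an elevation
gradient from valley grasslands to alpine terrain, climate covariates tied to
elevation through a lapse rate, compositional microhabitat covers, and
three-treatment song-playback trials (conspecific / congener / control).

Defaults follow the study-area envelope the package targets: plots between
120 and 2,620 m a.s.l., mean annual temperatures spanning roughly 1.9-13.6
degC, and annual rainfall of roughly 480-2,130 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .jsdm import ModelSpec, build_design_matrix

__all__ = [
    "HABITAT_CATEGORIES",
    "GradientConfig",
    "JsdmTrueParams",
    "PlaybackGenConfig",
    "simpson_index",
    "generate_sites",
    "generate_occurrences",
    "generate_playback_trials",
    "filter_by_forest_cover",
]

HABITAT_CATEGORIES = ("grassland", "high_shrub", "low_shrub",
                      "forest", "rock", "bare_ground")

TREATMENTS = ("conspecific", "congener", "control")

#: default per-covariate Gaussian noise (same units as the covariate)
_DEFAULT_NOISE = {
    "temp_mean": 0.8,      # degC
    "temp_min": 1.0,
    "temp_max": 1.0,
    "rainfall": 150.0,     # mm
    "roughness": 10.0,     # m
}


@dataclass(frozen=True)
class GradientConfig:
    """Parameters of the synthetic elevation gradient.

    ``temp_lapse`` is the change in mean annual temperature per km of
    elevation (negative; default -4.7 degC/km reproduces the 1.9-13.6 degC
    envelope over 120-2,620 m).  ``habitat_concentration`` gives the
    Dirichlet base weights for the six microhabitat covers; forest weight is
    additionally attenuated above the treeline (~1,400 m) and rock weight
    grows with elevation, which is what shapes the gradient in cover.
    """

    n_sites: int
    elevation_range: tuple[float, float] = (120.0, 2_620.0)
    temp_lapse: float = -4.7
    sea_level_temp: float = 14.2
    noise_sd: dict = field(default_factory=dict)
    habitat_concentration: dict = field(default_factory=lambda: {
        "grassland": 3.0, "high_shrub": 1.5, "low_shrub": 1.5,
        "forest": 2.5, "rock": 1.0, "bare_ground": 0.5,
    })
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        lo, hi = self.elevation_range
        if not lo < hi:
            raise ConfigurationError("elevation_range must satisfy low < high")
        missing = set(HABITAT_CATEGORIES) - set(self.habitat_concentration)
        if missing:
            raise ConfigurationError(
                f"habitat_concentration lacks categories: {sorted(missing)}")
        if any(w <= 0 for w in self.habitat_concentration.values()):
            raise ConfigurationError("habitat concentration weights must be > 0")
        unknown = set(self.noise_sd) - set(_DEFAULT_NOISE)
        if unknown:
            raise ConfigurationError(f"unknown noise_sd keys: {sorted(unknown)}")


def simpson_index(cover_fractions) -> float:
    """Microhabitat heterogeneity, ``1 - sum(p_i^2)``.

    0 for a single habitat type; approaches 1 as cover is spread evenly over
    many types (maximum ``1 - 1/k`` for ``k`` types).
    """
    p = np.asarray(cover_fractions, dtype=float)
    if (p < 0).any():
        raise ValidationError("cover fractions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValidationError(f"cover fractions must sum to 1 (got {p.sum()!r})")
    return float(1.0 - (p ** 2).sum())


def generate_sites(config: GradientConfig) -> pd.DataFrame:
    """Generate a site table of environmental covariates along the gradient.

    Deterministic given ``config.seed``.  Climate follows elevation through
    the configured lapse rate plus Gaussian noise; habitat covers are drawn
    from an elevation-modulated Dirichlet so they sum to one by construction;
    heterogeneity is the Simpson index of the covers.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    lo, hi = config.elevation_range
    noise = {**_DEFAULT_NOISE, **config.noise_sd}

    elevation = rng.uniform(lo, hi, n)
    latitude = rng.uniform(42.85, 43.25, n)
    longitude = rng.uniform(-6.9, -4.5, n)

    km = elevation / 1_000.0
    temp_mean = (config.sea_level_temp + config.temp_lapse * km
                 + rng.normal(0, noise["temp_mean"], n))
    temp_min = temp_mean - 6.5 + rng.normal(0, noise["temp_min"], n)
    temp_max = temp_mean + 7.5 + rng.normal(0, noise["temp_max"], n)
    rainfall = np.maximum(
        450.0 + 0.62 * elevation + rng.normal(0, noise["rainfall"], n), 100.0)
    slope = np.clip(np.abs(rng.normal(15.0, 9.0, n)), 0.0, 60.0)
    solar_radiation = np.clip(rng.normal(14_000.0, 2_500.0, n), 4_000.0, None)
    roughness = np.maximum(
        3.0 + 2.2 * slope + rng.normal(0, noise["roughness"], n), 0.0)

    # elevation-modulated Dirichlet: forest collapses above the treeline,
    # rock and bare ground take over at altitude
    base = np.array([config.habitat_concentration[c] for c in HABITAT_CATEGORIES])
    alpha = np.tile(base, (n, 1))
    treeline = 1.0 / (1.0 + np.exp((elevation - 1_400.0) / 250.0))
    alpine = (elevation - lo) / (hi - lo)
    alpha[:, HABITAT_CATEGORIES.index("forest")] *= np.maximum(2.0 * treeline, 0.02)
    alpha[:, HABITAT_CATEGORIES.index("rock")] *= 0.5 + 2.5 * alpine
    alpha[:, HABITAT_CATEGORIES.index("bare_ground")] *= 0.5 + 2.0 * alpine
    covers = np.vstack([rng.dirichlet(a) for a in alpha])

    heterogeneity = 1.0 - (covers ** 2).sum(axis=1)

    table = pd.DataFrame({
        "site_id": [f"site_{i:05d}" for i in range(n)],
        "latitude": latitude,
        "longitude": longitude,
        "elevation": elevation,
        "temp_mean": temp_mean,
        "temp_min": temp_min,
        "temp_max": temp_max,
        "rainfall": rainfall,
        "slope": slope,
        "solar_radiation": solar_radiation,
        "roughness": roughness,
    })
    for k, c in enumerate(HABITAT_CATEGORIES):
        table[f"cover_{c}"] = covers[:, k]
    table["habitat_heterogeneity"] = heterogeneity
    return table


@dataclass(frozen=True)
class JsdmTrueParams:
    """Ground-truth coefficients and residual correlation of the generator.

    ``beta`` has one row per species and one column per design-matrix column
    (intercept first), on the probit scale.  ``rho_resid`` must be a valid
    correlation matrix (symmetric positive definite, unit diagonal).
    """

    beta: np.ndarray
    rho_resid: np.ndarray

    def __post_init__(self):
        beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        rho = np.atleast_2d(np.asarray(self.rho_resid, dtype=float))
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "rho_resid", rho)
        if rho.shape[0] != rho.shape[1] or rho.shape[0] != beta.shape[0]:
            raise ValidationError("rho_resid must be square, one row per species")
        if not np.allclose(rho, rho.T, atol=1e-10):
            raise ValidationError("rho_resid must be symmetric")
        if not np.allclose(np.diag(rho), 1.0, atol=1e-10):
            raise ValidationError("rho_resid must have unit diagonal")
        off = rho[~np.eye(rho.shape[0], dtype=bool)]
        if off.size and (np.abs(off) >= 1.0).any():
            raise ValidationError("off-diagonal correlations must lie in (-1, 1)")
        try:
            np.linalg.cholesky(rho)
        except np.linalg.LinAlgError:
            raise ValidationError("rho_resid is not positive definite") from None


def generate_occurrences(sites: pd.DataFrame, spec: ModelSpec,
                         params: JsdmTrueParams, seed: int) -> pd.DataFrame:
    """Draw presence/absence from the latent multivariate-probit model.

    For each site a latent residual ``e ~ N(0, rho_resid)`` is drawn and
    species ``j`` is present iff ``x'beta_j + e_j > 0`` (ties have
    probability zero).  The design matrix is built from ``sites`` with the
    same centering/scaling convention the fitting code uses, so recovered
    coefficients are directly comparable with ``params.beta``.
    """
    design = build_design_matrix(sites, spec)
    beta = params.beta
    if beta.shape != (len(spec.species), design.values.shape[1]):
        raise ValidationError(
            f"beta shape {beta.shape} does not conform to "
            f"({len(spec.species)}, {design.values.shape[1]}) "
            "(species x design columns)")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(params.rho_resid)
    e = rng.standard_normal((len(sites), len(spec.species))) @ L.T
    latent = design.values @ beta.T + e
    occ = pd.DataFrame((latent > 0).astype(int), columns=list(spec.species))
    occ.insert(0, "site_id", sites["site_id"].to_numpy())
    return occ


@dataclass(frozen=True)
class PlaybackGenConfig:
    """Parameters of the synthetic playback experiment.

    ``group_means`` maps each treatment to its (mean approach distance in m,
    mean latency in s).  Responses are lognormal by default — strictly
    positive and right-skewed, matching field approach data — with
    ``sigma_log`` the log-scale dispersion shared by all groups.
    ``pre_mean`` is the mean pre-playback closest distance, common to all
    treatments (birds not yet stimulated).
    """

    n_per_group: int
    group_means: dict = field(default_factory=lambda: {
        "conspecific": (8.0, 60.0),
        "congener": (28.0, 180.0),
        "control": (30.0, 200.0),
    })
    sigma_log: float = 0.4
    family: str = "lognormal"
    species: str = "species_A"
    pre_mean: float = 55.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if set(self.group_means) != set(TREATMENTS):
            raise ConfigurationError(
                f"group_means must cover exactly {TREATMENTS}")
        for t, (d, lat) in self.group_means.items():
            if d <= 0 or lat <= 0:
                raise ConfigurationError(f"means for {t!r} must be > 0")
        if self.sigma_log < 0:
            raise ConfigurationError("sigma_log must be >= 0")
        if self.family not in ("lognormal", "normal"):
            raise ConfigurationError("family must be 'lognormal' or 'normal'")


def _positive_draws(rng, mean, sigma_log, n, family):
    """Strictly positive responses with the requested mean."""
    if sigma_log == 0:
        return np.full(n, float(mean))
    if family == "lognormal":
        mu = np.log(mean) - sigma_log ** 2 / 2.0  # mean-preserving
        return rng.lognormal(mu, sigma_log, n)
    draws = rng.normal(mean, sigma_log * mean, n)
    return np.maximum(draws, 1e-3)


def generate_playback_trials(config: PlaybackGenConfig) -> pd.DataFrame:
    """Balanced three-treatment playback trials, one row per tested male.

    Columns: trial_id, species, treatment, month (breeding season 3-7),
    hour (field window 7-16), min_distance_m, latency_s, pre_distance_m.
    Reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    i = 0
    for treatment in TREATMENTS:
        d_mean, l_mean = config.group_means[treatment]
        dist = _positive_draws(rng, d_mean, config.sigma_log,
                               config.n_per_group, config.family)
        lat = _positive_draws(rng, l_mean, config.sigma_log,
                              config.n_per_group, config.family)
        pre = _positive_draws(rng, config.pre_mean, config.sigma_log,
                              config.n_per_group, config.family)
        month = rng.integers(3, 8, config.n_per_group)
        hour = rng.integers(7, 17, config.n_per_group)
        for k in range(config.n_per_group):
            rows.append((f"trial_{i:04d}", config.species, treatment,
                         int(month[k]), int(hour[k]),
                         float(dist[k]), float(lat[k]), float(pre[k])))
            i += 1
    return pd.DataFrame(rows, columns=[
        "trial_id", "species", "treatment", "month", "hour",
        "min_distance_m", "latency_s", "pre_distance_m"])


def filter_by_forest_cover(sites: pd.DataFrame, occ: pd.DataFrame,
                           max_forest: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop survey plots whose forest cover is ``>= max_forest``.

    Heavily forested plots are unsuitable for open-habitat species and
    carry no information for the occupancy model; the retained plots are
    those with forest cover strictly below the threshold.  Row alignment
    between the two tables is preserved (and required on input).
    """
    if not 0.0 < max_forest <= 1.0:
        raise ValidationError("max_forest must lie in (0, 1]")
    if len(sites) != len(occ) or not np.array_equal(
            sites["site_id"].to_numpy(), occ["site_id"].to_numpy()):
        raise ValidationError("site ids of sites and occurrences are misaligned")
    keep = (sites["cover_forest"].to_numpy() < max_forest)
    return (sites.loc[keep].reset_index(drop=True),
            occ.loc[keep].reset_index(drop=True))
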