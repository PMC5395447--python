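"""End-to-end orchestration: data -> filter -> model selection -> inference -> report.

A single plain-text (YAML/JSON) config drives the full analysis in a fixed
stage order:

1. load or synthesise the survey (site table + occurrence matrix);
2. drop heavily forested plots;
3. stratified K-fold cross-validation over the candidate model specs and
   selection of the best predictor set by species-averaged AUC;
4. final joint-model fit on all retained plots;
5. environmental and residual correlation estimates;
6. pairwise C-scores;
7. load or synthesise playback trials and run the full behavioural battery
   (sign test, temporal confound check, Box-Cox + ANOVA/Tukey on distance,
   Kruskal-Wallis + Dunn on latency, effect sizes, segregation-scaled power);
8. write every artifact as CSV plus a machine-readable JSON report.

The master seed deterministically spawns per-stage seeds, so identical
config + seed reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cooccurrence import c_score, c_score_all_pairs
from .errors import ConfigurationError, ParapatryError
from .jsdm import (McmcConfig, ModelSpec, build_design_matrix,
                   correlation_table, fit_jsdm, posterior_summary)
from .modelsel import cross_validate, select_best
from .playback import (anova_tukey, boxcox_mle, check_response_to_conspecific,
                       cohens_d, kruskal_dunn, segregation_scaled_power,
                       temporal_covariate_check)
from .synth import (GradientConfig, JsdmTrueParams, PlaybackGenConfig,
                    filter_by_forest_cover, generate_occurrences,
                    generate_playback_trials, generate_sites)

__all__ = ["PipelineConfig", "RunReport", "validate_config", "load_config",
           "run_pipeline"]

log = logging.getLogger("parapatry")


class StageError(ParapatryError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    """Validated, in-memory form of the pipeline config file."""

    raw: dict
    seed: int
    outdir: Path

    @property
    def alpha(self) -> float:
        return float(self.raw.get("alpha", 0.05))

    @property
    def k_folds(self) -> int:
        return int(self.raw.get("k_folds", 5))


def load_config(path) -> dict:
    """Read a YAML (or JSON) pipeline config file."""
    import yaml
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("config file must contain a mapping")
    return cfg


def _survey_errors(cfg: dict) -> list[str]:
    errors = []
    survey = cfg.get("survey")
    if not isinstance(survey, dict):
        return ["missing 'survey' section"]
    has_files = "sites_csv" in survey or "occurrences_csv" in survey
    has_synth = "synth" in survey
    if has_files and has_synth:
        errors.append("survey: provide either CSV paths or a synth block, not both")
    elif has_files:
        for key in ("sites_csv", "occurrences_csv"):
            if key not in survey:
                errors.append(f"survey: {key} missing")
            elif not Path(survey[key]).exists():
                errors.append(f"survey: file not found: {survey[key]}")
    elif not has_synth:
        errors.append("survey: needs either sites_csv+occurrences_csv or a synth block")
    if has_synth:
        synth = survey["synth"]
        truth = synth.get("truth")
        if not isinstance(truth, dict):
            errors.append("survey.synth: missing 'truth' block (predictors/beta/rho)")
        else:
            for key in ("predictors", "beta", "rho"):
                if key not in truth:
                    errors.append(f"survey.synth.truth: {key} missing")
        if int(synth.get("n_sites", 0)) < 10:
            errors.append("survey.synth: n_sites must be >= 10")
    return errors


def validate_config(cfg: dict) -> list[str]:
    """All config problems at once (empty list means valid).

    Content problems are returned, never raised; cross-field checks include
    the forest threshold range, candidate-spec consistency, the MCMC
    schedule and — when data files are supplied — a stratification pre-check
    that every species has at least k presences and absences.
    """
    errors = []
    if "species" not in cfg or len(cfg.get("species") or []) < 2:
        errors.append("need a 'species' list with >= 2 names")
    errors.extend(_survey_errors(cfg))

    thr = cfg.get("forest_max_cover", 0.8)
    if not (isinstance(thr, (int, float)) and 0.0 < thr <= 1.0):
        errors.append(f"forest_max_cover must lie in (0, 1], got {thr!r}")

    cands = cfg.get("candidates")
    if not cands:
        errors.append("need at least one candidate model in 'candidates'")
    else:
        names = [c.get("name") for c in cands]
        if len(set(names)) != len(names):
            errors.append("candidate model names must be unique")
        for c in cands:
            if "predictors" not in c:
                errors.append(f"candidate {c.get('name')!r}: missing predictors")
            extra = set(c.get("quadratic", [])) - set(c.get("predictors", []))
            if extra:
                errors.append(f"candidate {c.get('name')!r}: quadratic terms "
                              f"{sorted(extra)} not among predictors")

    k = cfg.get("k_folds", 5)
    if not (isinstance(k, int) and k >= 2):
        errors.append(f"k_folds must be an integer >= 2, got {k!r}")

    alpha = cfg.get("alpha", 0.05)
    if not (isinstance(alpha, (int, float)) and 0 < alpha < 1):
        errors.append(f"alpha must lie in (0, 1), got {alpha!r}")

    mcmc = cfg.get("mcmc", {})
    try:
        McmcConfig(**{**_DEFAULT_MCMC, **mcmc, "seed": 0})
    except (TypeError, ParapatryError) as exc:
        errors.append(f"mcmc: {exc}")

    cs = cfg.get("c_score_source", "computed")
    if cs != "computed" and not (isinstance(cs, (int, float)) and 0 <= cs <= 1):
        errors.append("c_score_source must be 'computed' or a number in [0, 1]")

    pb = cfg.get("playback")
    if isinstance(pb, dict):
        if ("trials_csv" in pb) == ("synth" in pb):
            errors.append("playback: provide either trials_csv or a synth block")
        elif "trials_csv" in pb and not Path(pb["trials_csv"]).exists():
            errors.append(f"playback: file not found: {pb['trials_csv']}")

    # stratification pre-check on supplied occurrence data
    survey = cfg.get("survey") or {}
    if (isinstance(k, int) and k >= 2 and "occurrences_csv" in survey
            and Path(survey.get("occurrences_csv", "")).exists()):
        occ = pd.read_csv(survey["occurrences_csv"])
        for sp in cfg.get("species") or []:
            if sp in occ.columns:
                pres = int(occ[sp].sum())
                if pres < k or len(occ) - pres < k:
                    errors.append(
                        f"stratification pre-check: species {sp!r} has {pres} "
                        f"presences / {len(occ) - pres} absences; k={k} folds "
                        "are not constructible")
    return errors


_DEFAULT_MCMC = {"n_chains": 3, "n_iter": 6_000, "n_burnin": 3_000, "thin": 3,
                 "prior_precision": 0.001}


def _mcmc_from(cfg: dict, block: str, seed: int) -> McmcConfig:
    params = {**_DEFAULT_MCMC, **(cfg.get(block) or cfg.get("mcmc") or {})}
    params["seed"] = seed
    return McmcConfig(**params)


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([int(master), stage])
               .generate_state(1)[0] % (2 ** 31))


@dataclasses.dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    selected_model: str
    cv: list
    correlations: list
    c_scores: list
    playback: dict
    power: list
    provenance: dict
    files: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(cfg: dict, outdir, seed: int | None = None) -> RunReport:
    """Execute the full analysis; see the module docstring for the stages.

    Any stage failure is re-raised as :class:`StageError` tagged with the
    stage name.  Returns the report (also written to ``outdir/report.json``).
    """
    problems = validate_config(cfg)
    if problems:
        raise ConfigurationError("invalid config: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    species = list(cfg["species"])
    files: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame):
        # paths in the report are relative to outdir so that identical
        # config+seed produce byte-identical reports anywhere
        df.to_csv(outdir / name, index=False, float_format="%.10g")
        files[name.split(".")[0]] = name

    # -- stage 1: survey data -------------------------------------------
    stage = "survey"
    try:
        survey = cfg["survey"]
        if "synth" in survey:
            synth = survey["synth"]
            gradient_keys = {f.name for f in dataclasses.fields(GradientConfig)}
            gparams = {k: v for k, v in synth.items() if k in gradient_keys}
            gcfg = GradientConfig(**{**gparams,
                                     "n_sites": int(synth["n_sites"]),
                                     "seed": _stage_seed(seed, 1)})
            sites = generate_sites(gcfg)
            truth = synth["truth"]
            spec = ModelSpec("truth", truth["predictors"], species,
                             truth.get("quadratic", ()))
            rho = truth["rho"]
            if np.isscalar(rho):
                rho = np.eye(len(species)) * (1 - rho) + rho
            params = JsdmTrueParams(np.asarray(truth["beta"], float),
                                    np.asarray(rho, float))
            occ = generate_occurrences(sites, spec, params, _stage_seed(seed, 2))
        else:
            sites = pd.read_csv(survey["sites_csv"])
            occ = pd.read_csv(survey["occurrences_csv"])
        _write("sites.csv", sites)
        _write("occurrences.csv", occ)
        log.info("survey: %d sites, %d species", len(sites), len(species))
    except ParapatryError as exc:
        raise StageError(stage, exc) from exc

    # -- stage 2: forest-cover filter -----------------------------------
    stage = "filter"
    try:
        thr = float(cfg.get("forest_max_cover", 0.8))
        sites_f, occ_f = filter_by_forest_cover(sites, occ, thr)
        _write("sites_filtered.csv", sites_f)
        _write("occurrences_filtered.csv", occ_f)
        log.info("filter: retained %d/%d plots below forest cover %.2f",
                 len(sites_f), len(sites), thr)
    except ParapatryError as exc:
        raise StageError(stage, exc) from exc

    # -- stage 3: cross-validation model selection ----------------------
    stage = "model_selection"
    try:
        specs = [ModelSpec(c["name"], c["predictors"], species,
                           c.get("quadratic", ())) for c in cfg["candidates"]]
        cv_mcmc = _mcmc_from(cfg, "cv_mcmc", _stage_seed(seed, 3))
        results = cross_validate(specs, sites_f, occ_f, cfg.get("k_folds", 5),
                                 cv_mcmc, seed=_stage_seed(seed, 3))
        best = select_best(results)
        _write("cv_results.csv", pd.concat([r.to_frame() for r in results],
                                           ignore_index=True))
        log.info("model selection: best model %r", best)
    except ParapatryError as exc:
        raise StageError(stage, exc) from exc

    # -- stage 4: final fit ---------------------------------------------
    stage = "fit"
    try:
        best_spec = next(s for s in specs if s.name == best)
        mcmc = _mcmc_from(cfg, "mcmc", _stage_seed(seed, 4))
        design = build_design_matrix(sites_f, best_spec)
        post = fit_jsdm(design, occ_f, mcmc)
        _write("posterior_summary.csv", posterior_summary(post))
    except ParapatryError as exc:
        raise StageError(stage, exc) from exc

    # -- stage 5: correlation decomposition ------------------------------
    stage = "correlations"
    try:
        corr = correlation_table(post)
        _write("correlations.csv", corr)
    except ParapatryError as exc:
        raise StageError(stage, exc) from exc

    # -- stage 6: C-scores ----------------------------------------------
    stage = "c_scores"
    try:
        scores = c_score_all_pairs(occ_f[["site_id"] + species])
        _write("cscores.csv", pd.DataFrame(
            [dataclasses.asdict(s) for s in scores]))
        cs_cfg = cfg.get("c_score_source", "computed")
        if cs_cfg == "computed":
            pair_c = c_score(occ_f[["site_id"] + species],
                             species[0], species[1]).c_score
        else:
            pair_c = float(cs_cfg)
    except ParapatryError as exc:
        raise StageError(stage, exc) from exc

    # -- stage 7: playback battery --------------------------------------
    stage = "playback"
    playback_report: dict = {}
    power_rows: list[dict] = []
    try:
        pb = cfg.get("playback")
        if pb:
            if "synth" in pb:
                pb_keys = {f.name for f in dataclasses.fields(PlaybackGenConfig)}
                pcfg = PlaybackGenConfig(**{
                    **{k: v for k, v in pb["synth"].items() if k in pb_keys},
                    "seed": _stage_seed(seed, 7)})
                trials = generate_playback_trials(pcfg)
            else:
                trials = pd.read_csv(pb["trials_csv"])
            _write("playback_trials.csv", trials)

            consp = trials[trials["treatment"] == "conspecific"]
            sign = check_response_to_conspecific(consp)
            temporal = {
                resp: temporal_covariate_check(trials, resp)["p_value"].min()
                for resp in ("min_distance_m", "latency_s")}
            bc = boxcox_mle(trials["min_distance_m"].to_numpy())
            tdist = trials.assign(distance_bc=bc.transformed)
            dist_contrast = anova_tukey(tdist, "distance_bc")
            lat_contrast = kruskal_dunn(trials, "latency_s")

            contrast_rows = []
            for fam, res in (("ANOVA+Tukey", dist_contrast),
                             ("KruskalWallis+Dunn", lat_contrast)):
                contrast_rows.append({"family": fam, "term": "omnibus",
                                      "statistic": res.statistic,
                                      "p_value": res.p_value})
                for c in res.pairwise:
                    contrast_rows.append({"family": fam,
                                          "term": f"{c.group_a} vs {c.group_b}",
                                          "statistic": c.statistic,
                                          "p_value": c.p_value})
            _write("playback_contrasts.csv", pd.DataFrame(contrast_rows))

            alpha = float(cfg.get("alpha", 0.05))
            for resp in ("min_distance_m", "latency_s"):
                g1 = trials.loc[trials["treatment"] == "conspecific", resp]
                g2 = trials.loc[trials["treatment"] == "control", resp]
                eff = cohens_d(g1, g2)
                pw = segregation_scaled_power(abs(eff.d), pair_c,
                                              eff.n1, eff.n2, alpha)
                power_rows.append({"response": resp, "d": eff.d,
                                   "c_score": pair_c, "scaled_d": pw.scaled_d,
                                   "n1": eff.n1, "n2": eff.n2, "alpha": alpha,
                                   "power": pw.power, "adequate": pw.adequate})
            _write("power.csv", pd.DataFrame(power_rows))
            playback_report = {
                "sign_test": {"z": sign.statistic, "p": sign.p_value,
                              **sign.extras},
                "temporal_min_p": temporal,
                "boxcox_lambda": bc.lmbda,
                "anova_F": dist_contrast.statistic,
                "anova_p": dist_contrast.p_value,
                "kruskal_H": lat_contrast.statistic,
                "kruskal_p": lat_contrast.p_value,
            }
    except ParapatryError as exc:
        raise StageError(stage, exc) from exc

    # -- stage 8: report -------------------------------------------------
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=_jsonable).encode()).hexdigest()
    report = RunReport(
        selected_model=best,
        cv=[{"model": r.model, "mean_auc": r.mean_auc,
             "auc_mean": r.auc_mean, "auc_sd": r.auc_sd}
            for r in results],
        correlations=corr.to_dict("records"),
        c_scores=[dataclasses.asdict(s) for s in scores],
        playback=playback_report,
        power=power_rows,
        provenance={"config_sha256": cfg_hash, "seed": seed,
                    "package_version": __version__},
        files=files,
    )
    files["report"] = "report.json"
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True,
                  default=_jsonable)
    return report
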