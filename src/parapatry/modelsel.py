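"""Model comparison by stratified K-fold cross-validation with per-species AUC.

Candidate predictor sets are compared on their ability to discriminate
occupied from unoccupied sites: the data are split into k folds that
preserve each species' prevalence, the joint model is refitted on each
training set (with centering/scaling recomputed on training rows only, so no
information leaks into the held-out fold), and the rank-based AUC of the
marginal presence probabilities is averaged over folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .errors import ComputationError, StratificationError, ValidationError
from .jsdm import (McmcConfig, ModelSpec, build_design_matrix, fit_jsdm,
                   predict_marginal)

__all__ = [
    "FoldAssignment",
    "CvResult",
    "make_stratified_folds",
    "auc",
    "cross_validate",
    "select_best",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Site-to-fold mapping, folds labelled 1..k."""

    assignments: pd.Series  # index: site_id, values: fold label
    k: int

    def fold_sites(self, fold: int) -> np.ndarray:
        return self.assignments.index[self.assignments == fold].to_numpy()

    def mask(self, fold: int) -> np.ndarray:
        return (self.assignments == fold).to_numpy()


def _species_block(occ: pd.DataFrame) -> pd.DataFrame:
    return occ.drop(columns=["site_id"], errors="ignore")


def _deviation(counts: np.ndarray, targets: np.ndarray) -> float:
    """Worst absolute deviation of per-fold species counts from proportionality."""
    return float(np.abs(counts - targets).max()) if counts.size else 0.0


def make_stratified_folds(occ: pd.DataFrame, k: int, seed: int) -> FoldAssignment:
    """Random k folds preserving each species' prevalence.

    Sites are stratified on their joint presence/absence pattern across
    species (for two species: the four cells 00/01/10/11) and dealt
    cyclically into folds, which keeps fold sizes within one site of each
    other and each species' presences per fold within one of perfect
    proportionality.  The dealing order of strata is chosen (over all
    orderings and cyclic starting folds) to minimise the worst prevalence
    deviation, with a local swap repair as a fallback; ties are broken by the
    seeded RNG.

    Raises
    ------
    StratificationError
        If ``k < 2`` or some species has fewer than ``k`` presences or
        absences.
    """
    if k < 2:
        raise StratificationError("k must be >= 2")
    block = _species_block(occ)
    y = block.to_numpy()
    n = len(occ)
    for j, sp in enumerate(block.columns):
        pres = int(y[:, j].sum())
        if pres < k or n - pres < k:
            raise StratificationError(
                f"species {sp!r} has {pres} presences / {n - pres} absences; "
                f"both must be >= k={k}")
    rng = np.random.default_rng(seed)
    site_ids = (occ["site_id"].to_numpy() if "site_id" in occ.columns
                else occ.index.to_numpy())

    patterns = [tuple(row) for row in y]
    strata: dict[tuple, list[int]] = {}
    for i, p in enumerate(patterns):
        strata.setdefault(p, []).append(i)
    for members in strata.values():
        rng.shuffle(members)
    keys = list(strata.keys())
    targets = y.sum(axis=0) / k  # per-species presences per fold, ideal

    def deal(order, start):
        """Cyclic deal with a continuing cursor; returns fold index per site."""
        fold_of = np.empty(n, dtype=int)
        cursor = start
        for key in order:
            for i in strata[key]:
                fold_of[i] = cursor % k
                cursor += 1
        return fold_of

    def score(fold_of):
        counts = np.zeros((k, y.shape[1]))
        for f in range(k):
            counts[f] = y[fold_of == f].sum(axis=0)
        return _deviation(counts, targets[None, :])

    if len(keys) <= 5:
        orders = list(permutations(keys))
    else:  # too many strata to enumerate: sample orderings
        orders = [tuple(keys[i] for i in rng.permutation(len(keys)))
                  for _ in range(120)]
    best, best_dev = None, np.inf
    for order in orders:
        for start in range(k):
            fold_of = deal(order, start)
            dev = score(fold_of)
            if dev < best_dev - 1e-12:
                best, best_dev = fold_of, dev
    fold_of = best

    if best_dev > 1.0 + 1e-9:  # local repair: swap sites between folds
        fold_of = _swap_repair(fold_of, y, targets, k, rng)

    series = pd.Series(fold_of + 1, index=pd.Index(site_ids, name="site_id"))
    return FoldAssignment(series, k)


def _swap_repair(fold_of: np.ndarray, y: np.ndarray, targets: np.ndarray,
                 k: int, rng: np.random.Generator, max_iter: int = 500) -> np.ndarray:
    """Greedy size-preserving swaps reducing the worst prevalence deviation."""
    fold_of = fold_of.copy()
    counts = np.zeros((k, y.shape[1]))
    for f in range(k):
        counts[f] = y[fold_of == f].sum(axis=0)
    dev = np.abs(counts - targets[None, :]).max()
    for _ in range(max_iter):
        if dev <= 1.0 + 1e-9:
            break
        improved = False
        order = rng.permutation(len(fold_of))
        for u in order:
            fu = fold_of[u]
            for v in rng.permutation(len(fold_of))[:50]:
                fv = fold_of[v]
                if fu == fv or (y[u] == y[v]).all():
                    continue
                delta = y[u] - y[v]
                new_counts = counts.copy()
                new_counts[fu] -= delta
                new_counts[fv] += delta
                new_dev = np.abs(new_counts - targets[None, :]).max()
                if new_dev < dev - 1e-12:
                    counts = new_counts
                    fold_of[u], fold_of[v] = fv, fu
                    dev = new_dev
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return fold_of


def auc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve.

    Equals the probability that a random presence site scores above a random
    absence site, with ties counting one half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValidationError("labels and scores must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be 0/1")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ComputationError("AUC undefined with a single class")
    from scipy.stats import rankdata
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class CvResult:
    """Cross-validated per-species AUC of one candidate model."""

    model: str
    n_params: int
    fold_aucs: dict          # species -> list of per-fold AUCs
    auc_mean: dict           # species -> arithmetic mean over folds
    auc_sd: dict             # species -> sd over folds (ddof=1)

    @property
    def mean_auc(self) -> float:
        """Unweighted mean over species of the per-species mean AUC."""
        return float(np.mean(list(self.auc_mean.values())))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp, per_fold in self.fold_aucs.items():
            rows.append({"model": self.model, "species": sp,
                         "auc_mean": self.auc_mean[sp], "auc_sd": self.auc_sd[sp],
                         **{f"auc_fold_{i + 1}": v for i, v in enumerate(per_fold)}})
        return pd.DataFrame(rows)


def _derived_seed(base: int, *parts: int) -> int:
    state = np.random.SeedSequence([int(base)] + [int(p) for p in parts])
    return int(state.generate_state(1)[0] % (2 ** 31))


def cross_validate(specs: list[ModelSpec], sites: pd.DataFrame,
                   occ: pd.DataFrame, k: int, mcmc: McmcConfig,
                   seed: int | None = None) -> list[CvResult]:
    """K-fold cross-validated AUC for each candidate model.

    For every spec and fold the design matrix is rebuilt on the training
    rows only (recording their centering/scaling), the joint model refitted,
    and held-out sites scored with the training transform.  Fit errors are
    re-raised annotated with the offending spec and fold.
    """
    seed = mcmc.seed if seed is None else seed
    folds = make_stratified_folds(occ, k, _derived_seed(seed, 0xF01D))
    block = _species_block(occ)
    results = []
    for si, spec in enumerate(specs):
        per_fold: dict[str, list[float]] = {sp: [] for sp in spec.species}
        for f in range(1, k + 1):
            test_mask = folds.mask(f)
            train_sites = sites.loc[~test_mask].reset_index(drop=True)
            train_occ = occ.loc[~test_mask].reset_index(drop=True)
            test_sites = sites.loc[test_mask].reset_index(drop=True)
            fold_mcmc = McmcConfig(
                n_chains=mcmc.n_chains, n_iter=mcmc.n_iter,
                n_burnin=mcmc.n_burnin, thin=mcmc.thin,
                seed=_derived_seed(seed, si, f),
                prior_precision=mcmc.prior_precision)
            try:
                design = build_design_matrix(train_sites, spec)
                post = fit_jsdm(design, train_occ, fold_mcmc)
                probs = predict_marginal(post, test_sites)
            except Exception as exc:
                raise type(exc)(
                    f"model {spec.name!r}, fold {f}: {exc}") from exc
            for sp in spec.species:
                labels = block.loc[test_mask, sp].to_numpy()
                per_fold[sp].append(auc(labels, probs[sp].to_numpy()))
        means = {sp: float(np.mean(v)) for sp, v in per_fold.items()}
        sds = {sp: float(np.std(v, ddof=1)) for sp, v in per_fold.items()}
        results.append(CvResult(spec.name, spec.n_params, per_fold, means, sds))
    return results


def select_best(results: list[CvResult], rule: str = "mean_auc") -> str:
    """Name of the model with the highest species-averaged mean AUC.

    Ties are broken deterministically: fewer parameters first, then
    lexicographic model name.
    """
    if not results:
        raise ValidationError("no cross-validation results to select from")
    if rule != "mean_auc":
        raise ValidationError(f"unknown selection rule {rule!r}")
    ranked = sorted(results, key=lambda r: (-r.mean_auc, r.n_params, r.model))
    return ranked[0].model
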