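"""Subject-level cross-validation for the penalized win-ratio path.

Pairs built from a common subject pool are correlated, and the pair set
grows quadratically in n, so partitioning *pairs* into CV folds leaks
information between analysis and validation sets and overstates accuracy.
Valid tuning partitions *subjects*: for fold k the path is fitted on pairs
formed entirely outside the fold and validated, via the generalized
concordance index, on pairs formed entirely inside it.  Cross-fold pairs
are used by neither side.

:func:`naive_pair_cv` implements the pair-level procedure anyway, purely as
a cautionary demonstration of the overfitting it produces.  Do not use it
to tune a model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .concordance import WinScore, concordance_index
from .data_model import Dataset
from .fit import FitConfig, fit_path, lambda_max
from .pairwise import build_pair_set


@dataclass
class FoldPlan:
    """Subject-level fold assignment, stratified by outcome status."""

    K: int
    assignment: dict  # subject_id -> fold index in 0..K-1
    seed: int | None = None

    def fold_ids(self, k: int) -> list:
        return [sid for sid, f in self.assignment.items() if f == k]


@dataclass
class CVResult:
    """Per-lambda validation concordance, averaged over folds."""

    lambdas: np.ndarray
    mean_concordance: np.ndarray
    fold_concordance: np.ndarray   # (K, n_lambda), NaN for dropped folds
    lambda_opt: float

    def to_frame(self):
        import pandas as pd
        rows = []
        for k in range(self.fold_concordance.shape[0]):
            for lam, c in zip(self.lambdas, self.fold_concordance[k]):
                rows.append((lam, k, c))
        df = pd.DataFrame(rows, columns=["lambda", "fold", "fold_concordance"])
        mean = pd.DataFrame({"lambda": self.lambdas,
                             "mean_concordance": self.mean_concordance})
        return df.merge(mean, on="lambda")


def make_folds(data: Dataset, K: int = 10, seed: int | None = None) -> FoldPlan:
    """Random K-fold partition of subjects, stratified on outcome status so
    deaths / nonfatal-only / event-free subjects spread evenly (within one)
    across folds."""
    n = len(data)
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of subjects ({n})")
    labels = np.array(data.outcome_statuses())
    ids = np.array(data.subject_ids, dtype=object)
    assignment = {}
    if K == n:
        for k, sid in enumerate(ids):
            assignment[sid] = k
    else:
        skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            # strata smaller than K are still spread as evenly as possible
            warnings.simplefilter("ignore", UserWarning)
            for k, (_, val) in enumerate(skf.split(np.zeros(n), labels)):
                for sid in ids[val]:
                    assignment[sid] = k
    return FoldPlan(K=K, assignment=assignment, seed=seed)


def _shared_grid(data: Dataset, config: FitConfig) -> np.ndarray:
    """Lambda grid computed once from the full training pair set, reused in
    every fold so the per-fold curves share an x-axis."""
    if config.lambda_grid is not None:
        return np.asarray(config.lambda_grid, dtype=float)
    pairs = build_pair_set(data)
    lmax = lambda_max(pairs, config.alpha, config.standardize)
    if lmax <= 0:
        return np.array([0.0])
    return np.geomspace(lmax, lmax * config.lambda_min_ratio, config.n_lambda)


def _select_lambda(lambdas: np.ndarray, mean_c: np.ndarray) -> float:
    # grid is decreasing; argmax returns the first (largest-lambda) maximizer
    return float(lambdas[int(np.nanargmax(mean_c))])


def cv_concordance(data: Dataset, plan: FoldPlan,
                   config: FitConfig = FitConfig()) -> CVResult:
    """K-fold subject-level CV of the penalized path.

    For each fold the path is fitted on the analysis pairs (both members
    outside the fold) over the shared grid and scored on the validation
    pairs (both members inside the fold); the optimal lambda maximizes the
    unweighted fold-mean concordance, ties resolved to the largest lambda
    (the sparser model).
    """
    grid = _shared_grid(data, config)
    cfg = FitConfig(alpha=config.alpha, lambda_grid=grid,
                    standardize=config.standardize, tol=config.tol,
                    max_iter=config.max_iter)
    all_ids = set(data.subject_ids)
    fold_c = np.full((plan.K, len(grid)), np.nan)
    for k in range(plan.K):
        val_ids = plan.fold_ids(k)
        train_ids = sorted(all_ids - set(val_ids), key=str)
        assert not set(val_ids) & set(train_ids)
        val_data = data.subset(val_ids)
        train_data = data.subset(train_ids)
        try:
            val_pairs = build_pair_set(val_data)
        except ValueError:
            val_pairs = None
        if val_pairs is None or len(val_pairs) == 0:
            warnings.warn(f"fold {k}: no comparable validation pairs; dropped")
            continue
        train_pairs = build_pair_set(train_data)
        path = fit_path(train_pairs, cfg)
        Z_val = val_data.covariate_matrix()
        ids_val = np.array(val_data.subject_ids, dtype=object)
        for m, beta in enumerate(path.betas):
            scores = WinScore(ids=ids_val, win=Z_val @ beta)
            fold_c[k, m] = concordance_index(val_pairs, scores)
    if np.isnan(fold_c).all():
        raise RuntimeError("all folds had empty validation pair sets")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_c = np.nanmean(fold_c, axis=0)
    return CVResult(lambdas=grid, mean_concordance=mean_c,
                    fold_concordance=fold_c,
                    lambda_opt=_select_lambda(grid, mean_c))


def naive_pair_cv(data: Dataset, K: int = 10, seed: int | None = None,
                  config: FitConfig = FitConfig()) -> CVResult:
    """Pair-level K-fold CV — the WRONG way, kept as a demonstration.

    Pairs (not subjects) are partitioned into folds and the metric is
    pairwise win/loss classification accuracy.  Because validation pairs
    share subjects with analysis pairs, the curve is biased toward
    overfitting: accuracy keeps climbing as lambda shrinks.  The lambda
    grid matches the subject-level procedure so the curves are comparable.
    """
    pairs = build_pair_set(data)
    if len(pairs) == 0:
        raise RuntimeError("no comparable pairs")
    grid = _shared_grid(data, config)
    cfg = FitConfig(alpha=config.alpha, lambda_grid=grid,
                    standardize=config.standardize, tol=config.tol,
                    max_iter=config.max_iter)
    kf = KFold(n_splits=min(K, len(pairs)), shuffle=True, random_state=seed)
    fold_c = np.full((kf.get_n_splits(), len(grid)), np.nan)
    for k, (tr, va) in enumerate(kf.split(np.zeros(len(pairs)))):
        path = fit_path(pairs.take(tr), cfg)
        val = pairs.take(va)
        sign = 2.0 * val.delta - 1.0
        for m, beta in enumerate(path.betas):
            margin = sign * (val.z_diff @ beta)
            fold_c[k, m] = np.mean((margin > 0) + 0.5 * (margin == 0))
    mean_c = np.nanmean(fold_c, axis=0)
    return CVResult(lambdas=grid, mean_concordance=mean_c,
                    fold_concordance=fold_c,
                    lambda_opt=_select_lambda(grid, mean_c))
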