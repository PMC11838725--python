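"""Regularized Cox regression for time to the first event — the benchmark
the win-ratio model is compared against.

The hierarchical outcome is collapsed to a composite first-event view
(earlier of death and first nonfatal event, censored otherwise) and an
elastic-net penalized Cox path is fitted; the penalized partial-likelihood
path itself is delegated to scikit-survival's Coxnet implementation.  The
penalty is tuned on the same subject-level folds as the win-ratio model,
by Harrell's C-index of the linear predictor on the validation fold's
first-event view, so the two methods are compared like for like.  The Cox
linear predictor is a risk score (higher = worse); its negative serves as
the win score when the fitted model is evaluated with the generalized
concordance index on the hierarchical outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .concordance import ConcordanceReport, WinScore, component_concordance
from .crossval import FoldPlan
from .data_model import Dataset
from .fit import FitConfig
from .pairwise import build_pair_set


@dataclass
class FirstEventView:
    """Composite first-event time and indicator per subject."""

    ids: np.ndarray
    time: np.ndarray
    event: np.ndarray  # bool: the minimum is an event, not censoring

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "time": self.time,
                             "event": self.event.astype(int)})


def to_first_event(data: Dataset) -> FirstEventView:
    """Collapse each history to min(death, first nonfatal, censoring)."""
    ids, times, events = [], [], []
    for r in data.records:
        t_first = min(r.first_nonfatal, r.obs_time)
        ids.append(r.subject_id)
        times.append(t_first)
        events.append(bool(r.nonfatal_times) or r.death_observed)
    return FirstEventView(ids=np.array(ids, dtype=object),
                          time=np.array(times, dtype=float),
                          event=np.array(events, dtype=bool))


def _coxnet(alpha_or_grid, l1_ratio):
    # Coxnet requires a strictly positive l1 mixing weight
    kw = dict(l1_ratio=max(l1_ratio, 0.01), tol=1e-7, max_iter=100_000)
    if isinstance(alpha_or_grid, np.ndarray):
        kw["alphas"] = alpha_or_grid
    else:
        kw["n_alphas"] = alpha_or_grid
        kw["alpha_min_ratio"] = 1e-3
    return CoxnetSurvivalAnalysis(**kw)


def fit_cox_lasso_cv(data: Dataset, plan: FoldPlan,
                     config: FitConfig = FitConfig()
                     ) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Penalized first-event Cox path with subject-level CV.

    Returns ``(beta, lambda_opt, cv_curve)``: coefficients at the optimal
    penalty, the penalty itself (largest among maximizers of mean
    validation Harrell C), and the per-lambda mean-C curve.
    """
    fe = to_first_event(data)
    if not fe.event.any():
        raise ValueError("no events in the data; Cox model undefined")
    Z = data.covariate_matrix()
    y = Surv.from_arrays(event=fe.event, time=fe.time)
    full = _coxnet(config.n_lambda, config.alpha)
    full.fit(Z, y)
    grid = np.asarray(full.alphas_, dtype=float)

    ids = np.array(data.subject_ids, dtype=object)
    id_to_pos = {sid: i for i, sid in enumerate(ids)}
    fold_c = np.full((plan.K, len(grid)), np.nan)
    for k in range(plan.K):
        val_pos = np.array([id_to_pos[s] for s in plan.fold_ids(k)])
        mask = np.zeros(len(ids), dtype=bool)
        mask[val_pos] = True
        if fe.event[~mask].sum() == 0 or mask.sum() < 2:
            warnings.warn(f"fold {k}: unusable for Cox CV; dropped")
            continue
        est = _coxnet(grid, config.alpha)
        try:
            est.fit(Z[~mask], Surv.from_arrays(event=fe.event[~mask],
                                               time=fe.time[~mask]))
        except Exception as e:  # noqa: BLE001
            warnings.warn(f"fold {k}: Coxnet failed ({e}); dropped")
            continue
        for m, lam in enumerate(grid):
            try:
                lp = est.predict(Z[mask], alpha=lam)
            except ValueError:
                continue
            try:
                c = concordance_index_censored(
                    fe.event[mask], fe.time[mask], lp)[0]
            except Exception:  # no comparable pairs in the fold
                continue
            fold_c[k, m] = c
    if np.isnan(fold_c).all():
        raise RuntimeError("Cox cross-validation failed on every fold")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_c = np.nanmean(fold_c, axis=0)
    opt_idx = int(np.nanargmax(mean_c))  # grid descending: largest lambda wins
    lambda_opt = float(grid[opt_idx])
    beta = np.asarray(full.coef_)[:, opt_idx].copy()
    curve = pd.DataFrame({"lambda": grid, "mean_concordance": mean_c})
    return beta, lambda_opt, curve


def evaluate_cox_on_hierarchy(beta: np.ndarray, test: Dataset
                              ) -> ConcordanceReport:
    """Score the Cox linear predictor against the hierarchical outcome with
    the same generalized / component-wise C-index as the win-ratio model.
    The linear predictor is a risk score, so the win score is its
    negative."""
    beta = np.asarray(beta, dtype=float)
    Z = test.covariate_matrix()
    scores = WinScore(ids=np.array(test.subject_ids, dtype=object),
                      win=-(Z @ beta))
    return component_concordance(build_pair_set(test), scores)
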