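"""Final-model refit, variable importance, and risk stratification.

After cross-validation selects the penalty, the path is refitted on the
full training data at that penalty.  The linear predictor gives each
subject a win score (negative = risk score); covariates are ranked by the
magnitude of their standardized coefficients; and the risk-score spectrum
is cut at training quantiles into L strata, within which Kaplan-Meier
curves for overall survival and event-free survival provide a
nonparametric prognosis (the pairwise model itself has no baseline
function to predict absolute event probabilities from).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .concordance import WinScore
from .data_model import Dataset
from .fit import FitConfig, fit_at
from .pairwise import build_pair_set


@dataclass
class FinalModel:
    """Refit of the penalized model at the selected penalty."""

    beta: np.ndarray               # original covariate scale
    lambda_opt: float
    scale_factors: np.ndarray
    covariate_names: list[str]
    alpha: float

    @property
    def selected(self) -> np.ndarray:
        return self.beta != 0


def refit_final(data: Dataset, lambda_opt: float,
                config: FitConfig = FitConfig()) -> FinalModel:
    """Refit on all training subjects at ``lambda_opt``, warm-starting down
    the automatic grid so the coefficients match the CV path entry."""
    pairs = build_pair_set(data)
    path = fit_at(pairs, lambda_opt, config)
    return FinalModel(beta=path.betas[-1], lambda_opt=float(lambda_opt),
                      scale_factors=path.scale_factors,
                      covariate_names=list(pairs.covariate_names),
                      alpha=config.alpha)


def variable_importance(beta: np.ndarray, scale_factors: np.ndarray,
                        names: list[str]) -> pd.DataFrame:
    """Importance = |coefficient on the standardized scale|, i.e.
    ``|beta_j| * scale_j``; sorted descending, ties broken by name.

    Zero-variance covariates (scale reported as degenerate) get importance
    0 with a warning.
    """
    beta = np.asarray(beta, dtype=float)
    scale = np.asarray(scale_factors, dtype=float)
    if not (len(beta) == len(scale) == len(names)):
        raise ValueError("beta, scale_factors and names must align")
    if np.any(scale <= 0):
        warnings.warn("zero-variance covariate; importance set to 0")
    importance = np.abs(beta) * np.where(scale > 0, scale, 0.0)
    df = pd.DataFrame({"covariate": names, "importance": importance,
                       "coefficient": beta, "selected": beta != 0})
    return (df.sort_values(["importance", "covariate"],
                           ascending=[False, True])
              .reset_index(drop=True))


def risk_scores(data: Dataset, beta: np.ndarray) -> WinScore:
    """Per-subject win score ``beta'z`` (risk = its negative)."""
    beta = np.asarray(beta, dtype=float)
    if len(beta) != data.n_covariates:
        raise ValueError("beta length does not match covariate count")
    Z = data.covariate_matrix()
    return WinScore(ids=np.array(data.subject_ids, dtype=object),
                    win=Z @ beta)


@dataclass
class RiskStrata:
    """Quantile-based risk strata with per-stratum Kaplan-Meier prognosis.

    ``cut_points`` are the L-1 training risk-score quantiles; stratum
    indices run 1 (lowest risk) to L (highest risk), membership left-closed
    on the cut points (a score equal to a cut point joins the upper
    stratum).  ``curves[s]`` is a DataFrame (time, surv_overall,
    surv_event_free).
    """

    L: int
    cut_points: np.ndarray
    curves: dict[int, pd.DataFrame]
    counts: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        out = []
        for s, df in self.curves.items():
            d = df.copy()
            d.insert(0, "stratum", s)
            out.append(d)
        return pd.concat(out, ignore_index=True)


def _km_curve(durations, events) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(),
                         "survival": sf.iloc[:, 0].to_numpy()})


def stratify_and_km(train: Dataset, scores: WinScore, L: int = 3) -> RiskStrata:
    """Cut the training risk-score spectrum at the j/L quantiles and fit
    product-limit curves per stratum.

    Overall survival treats observed death as the event; event-free
    survival treats the earlier of first nonfatal event and death as the
    event, censoring otherwise.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    r = scores.lookup(train.subject_ids) * -1.0
    if np.ptp(r) == 0 and L > 1:
        warnings.warn("degenerate risk scores (all equal); using one stratum")
        L = 1
    cuts = np.quantile(r, [j / L for j in range(1, L)]) if L > 1 else np.array([])
    stratum = np.searchsorted(cuts, r, side="right")  # 0..L-1
    X = np.array([rec.obs_time for rec in train.records])
    dead = np.array([rec.death_observed for rec in train.records])
    t_first = np.array([min(rec.first_nonfatal, rec.obs_time)
                        for rec in train.records])
    any_event = np.array([rec.death_observed or bool(rec.nonfatal_times)
                          for rec in train.records])
    curves, counts = {}, {}
    for s in range(L):
        mask = stratum == s
        n_s = int(mask.sum())
        counts[s + 1] = n_s
        if n_s == 0:
            curves[s + 1] = pd.DataFrame(
                {"time": [0.0], "surv_overall": [1.0], "surv_event_free": [1.0]})
            continue
        if n_s < 10:
            warnings.warn(f"stratum {s + 1} has only {n_s} subjects")
        overall = _km_curve(X[mask], dead[mask])
        eventfree = _km_curve(t_first[mask], any_event[mask])
        merged = pd.merge(
            overall.rename(columns={"survival": "surv_overall"}),
            eventfree.rename(columns={"survival": "surv_event_free"}),
            on="time", how="outer").sort_values("time")
        merged = merged.ffill().fillna(1.0).reset_index(drop=True)
        curves[s + 1] = merged
    return RiskStrata(L=L, cut_points=cuts, curves=curves, counts=counts)


def predict_stratum(strata: RiskStrata, score: float
                    ) -> tuple[int, pd.DataFrame]:
    """Map a risk score to its stratum (1 = lowest risk) and return the
    stratum's prognosis curves.  Scores beyond the training range map to
    the outer strata."""
    s = int(np.searchsorted(strata.cut_points, score, side="right")) + 1
    return s, strata.curves[s]
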