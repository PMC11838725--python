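"""Generalized concordance index for win scores.

The fitted linear predictor ``w_i = beta' z_i`` is the subject's "win
score" (its negative is the risk score).  Over a set of comparable pairs,
concordance is the fraction of pairs whose winner has the strictly higher
win score, with half credit for exactly tied scores — a direct analogue of
Harrell's C-index for hierarchical outcomes.  Because wins can be decided
at either tier of the hierarchy, a component-wise index restricted to
death-decided or nonfatal-decided pairs is reported alongside the overall
index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .pairwise import PairSet, Tier


@dataclass
class WinScore:
    """Per-subject win scores ``w = beta'z`` (risk score is ``-w``)."""

    ids: np.ndarray
    win: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.win = np.asarray(self.win, dtype=float)
        if len(self.ids) != len(self.win):
            raise ValueError("ids and scores must align")

    @property
    def risk(self) -> np.ndarray:
        return -self.win

    def lookup(self, ids) -> np.ndarray:
        s = pd.Series(self.win, index=pd.Index(self.ids))
        out = s.reindex(pd.Index(np.asarray(ids, dtype=object)))
        if out.isna().any():
            raise KeyError("score requested for unknown subject id")
        return out.to_numpy()


@dataclass
class ConcordanceReport:
    """Overall and component-wise concordance; a component is None when no
    pair was decided at that tier (absence, not 0.5)."""

    overall: float | None
    death: float | None
    nonfatal: float | None
    n_pairs_overall: int
    n_pairs_death: int
    n_pairs_nonfatal: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"component": ["death", "nonfatal", "overall"],
             "concordance": [self.death, self.nonfatal, self.overall],
             "n_pairs": [self.n_pairs_death, self.n_pairs_nonfatal,
                         self.n_pairs_overall]}
        )


def win_probability(z_i, z_j, beta) -> float:
    """Model win probability mu(z_i, z_j; beta) for subject i over j given
    comparability: the logistic function of ``beta'(z_i - z_j)``."""
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    beta = np.asarray(beta, dtype=float)
    return float(expit(beta @ (z_i - z_j)))


def _pair_scores(pairs: PairSet, scores: WinScore):
    w = scores.lookup(pairs.subject_ids)
    return w[pairs.i_idx], w[pairs.j_idx]


def concordance_index(pairs: PairSet, scores: WinScore) -> float:
    """Generalized C-index of the win score over the comparable pairs.

    Exact floating-point score equality earns the half credit; ties arise
    structurally (zero coefficients, identical covariates) and a tolerance
    would make the credit seed-dependent.
    """
    if len(pairs) == 0:
        raise ValueError("concordance undefined on an empty pair set")
    wi, wj = _pair_scores(pairs, scores)
    sign = 2.0 * pairs.delta - 1.0
    diff = wi - wj
    correct = (sign * diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(correct / len(pairs))


def component_concordance(pairs: PairSet, scores: WinScore) -> ConcordanceReport:
    """Concordance overall and split by the tier that decided each pair."""
    death_mask = pairs.tier == Tier.DEATH
    nonfatal_mask = pairs.tier == Tier.NONFATAL

    def _sub(mask):
        if mask.sum() == 0:
            return None
        return concordance_index(pairs.take(mask), scores)

    return ConcordanceReport(
        overall=_sub(np.ones(len(pairs), dtype=bool)) if len(pairs) else None,
        death=_sub(death_mask),
        nonfatal=_sub(nonfatal_mask),
        n_pairs_overall=len(pairs),
        n_pairs_death=int(death_mask.sum()),
        n_pairs_nonfatal=int(nonfatal_mask.sum()),
    )
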