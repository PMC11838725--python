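"""Two-tiered win rule and construction of the comparable-pair set.

For a pair of subjects evaluated over their shared observation window
``t = min(X_i, X_j)``, death is compared first: a subject who survives the
other's observed death wins; if both died, the later death wins.  Only when
neither death falls inside the window is the first nonfatal event compared,
the later (or absent) first event winning.  Exact ties at a tier give an
overall tie and the pair is not comparable.

Event times *at* the window boundary count as inside the window
(window-inclusive convention); between-subject comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .data_model import Dataset, SubjectRecord

I_WINS = 1
J_WINS = -1
TIE = 0


class Tier(IntEnum):
    """Which tier of the hierarchy decided a comparison."""
    NONE = 0
    DEATH = 1
    NONFATAL = 2


def win_indicator(rec_i: SubjectRecord, rec_j: SubjectRecord,
                  t: float) -> tuple[int, Tier]:
    """Evaluate the two-tiered win function at time ``t``.

    Returns ``(result, tier)`` with result ``1`` if subject i wins, ``-1``
    if subject j wins, ``0`` for a tie; ``tier`` names the deciding tier
    (``Tier.NONE`` for ties).

    ``t`` must not exceed the observation time of a subject who is
    censored alive, since that history is unknown beyond it; an observed
    death fixes the history at all later times.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    for rec in (rec_i, rec_j):
        if not rec.death_observed and t > rec.obs_time:
            raise ValueError(
                "t exceeds a censored observation time; history unknown on [0,t]")
    di = rec_i.death_observed and rec_i.obs_time <= t
    dj = rec_j.death_observed and rec_j.obs_time <= t
    if di and dj:
        if rec_i.obs_time > rec_j.obs_time:
            return I_WINS, Tier.DEATH
        if rec_i.obs_time < rec_j.obs_time:
            return J_WINS, Tier.DEATH
        return TIE, Tier.NONE
    if di:
        return J_WINS, Tier.DEATH
    if dj:
        return I_WINS, Tier.DEATH
    ti = rec_i.first_nonfatal if rec_i.first_nonfatal <= t else np.inf
    tj = rec_j.first_nonfatal if rec_j.first_nonfatal <= t else np.inf
    if ti > tj:
        return I_WINS, Tier.NONFATAL
    if ti < tj:
        return J_WINS, Tier.NONFATAL
    return TIE, Tier.NONE


@dataclass
class PairSet:
    """The comparable-pair set: every unordered subject pair whose shared
    observation window yields a strict win/loss.

    Pairs are stored in canonical order (i before j by sorted subject id);
    ``delta`` is 1 when subject i wins, 0 when subject j wins.  ``z_diff``
    holds ``z_i - z_j``.
    """

    subject_ids: np.ndarray          # ids in the sort order used for pairing
    i_idx: np.ndarray                # index into subject_ids
    j_idx: np.ndarray
    delta: np.ndarray                # uint8, 1 = i wins
    z_diff: np.ndarray               # (n_pairs, p)
    shared_time: np.ndarray
    tier: np.ndarray                 # Tier codes
    covariate_names: list[str]

    def __len__(self) -> int:
        return len(self.delta)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def i_ids(self) -> np.ndarray:
        return self.subject_ids[self.i_idx]

    @property
    def j_ids(self) -> np.ndarray:
        return self.subject_ids[self.j_idx]

    def take(self, index) -> "PairSet":
        """Pair subset (used e.g. by pair-level fold partitioning)."""
        return PairSet(
            subject_ids=self.subject_ids,
            i_idx=self.i_idx[index],
            j_idx=self.j_idx[index],
            delta=self.delta[index],
            z_diff=self.z_diff[index],
            shared_time=self.shared_time[index],
            tier=self.tier[index],
            covariate_names=self.covariate_names,
        )

    def to_frame(self):
        """Debug dump of the pair set."""
        import pandas as pd
        return pd.DataFrame({
            "i_id": self.i_ids,
            "j_id": self.j_ids,
            "delta": self.delta.astype(int),
            "tier": [Tier(t).name.lower() for t in self.tier],
            "shared_time": self.shared_time,
        })


def build_pair_set(data: Dataset) -> PairSet:
    """Enumerate all unordered subject pairs, evaluate the win rule at the
    shared observation window and keep the non-ties.

    Vectorized over the second pair member; memory stays O(n + |R| p).
    """
    n = len(data)
    if n < 2:
        raise ValueError("need at least 2 subjects to form pairs")
    order = np.argsort(np.array([str(s) for s in data.subject_ids]), kind="stable")
    recs = [data.records[k] for k in order]
    ids = np.array([r.subject_id for r in recs], dtype=object)
    X = np.array([r.obs_time for r in recs])
    dead = np.array([r.death_observed for r in recs])
    T1 = np.array([r.first_nonfatal for r in recs])
    Z = np.array([r.covariates for r in recs], dtype=float)

    out_i, out_j, out_d, out_t, out_tier = [], [], [], [], []
    for i in range(n - 1):
        j = np.arange(i + 1, n)
        t = np.minimum(X[i], X[j])
        di = dead[i] & (X[i] <= t)
        dj = dead[j] & (X[j] <= t)
        res = np.zeros(len(j), dtype=np.int8)
        tier = np.zeros(len(j), dtype=np.int8)
        both = di & dj
        res[both & (X[i] > X[j])] = I_WINS
        res[both & (X[i] < X[j])] = J_WINS
        only_i = di & ~dj
        only_j = dj & ~di
        res[only_i] = J_WINS      # i died within window, j survives it
        res[only_j] = I_WINS
        neither = ~di & ~dj
        ti = np.where(T1[i] <= t, T1[i], np.inf)
        tj = np.where(T1[j] <= t, T1[j], np.inf)
        res[neither & (ti > tj)] = I_WINS
        res[neither & (ti < tj)] = J_WINS
        decided = res != 0
        tier[decided & (both | only_i | only_j)] = Tier.DEATH
        tier[decided & neither] = Tier.NONFATAL
        keep = np.flatnonzero(decided)
        if len(keep):
            out_i.append(np.full(len(keep), i))
            out_j.append(j[keep])
            out_d.append((res[keep] == I_WINS).astype(np.uint8))
            out_t.append(t[keep])
            out_tier.append(tier[keep])

    if out_i:
        i_idx = np.concatenate(out_i)
        j_idx = np.concatenate(out_j)
        delta = np.concatenate(out_d)
        shared = np.concatenate(out_t)
        tiers = np.concatenate(out_tier)
        z_diff = Z[i_idx] - Z[j_idx]
    else:
        p = data.n_covariates
        i_idx = j_idx = np.empty(0, dtype=int)
        delta = np.empty(0, dtype=np.uint8)
        shared = np.empty(0)
        tiers = np.empty(0, dtype=np.int8)
        z_diff = np.empty((0, p))
    return PairSet(
        subject_ids=ids,
        i_idx=i_idx,
        j_idx=j_idx,
        delta=delta,
        z_diff=z_diff,
        shared_time=shared,
        tier=tiers,
        covariate_names=list(data.covariate_names),
    )
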