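"""Domain types and long-format table I/O for hierarchical composite endpoints.

A subject's outcome history is right-censored follow-up with a terminal
status (death or censoring) and zero or more nonfatal event times before
the terminal time.  The long-format table convention is one row per event:

    id, time, status, <covariate columns...>

with status 1 = death, 2 = nonfatal event, 0 = censoring.  Each subject has
exactly one terminal row (status 0 or 1) at their latest time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

STATUS_CENSOR = 0
STATUS_DEATH = 1
STATUS_NONFATAL = 2

#: Mutually exclusive outcome-status categories used for stratification.
STATUS_CATEGORIES = ("death", "nonfatal", "event_free")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's censored outcome history plus baseline covariates.

    Parameters
    ----------
    subject_id
        Opaque identifier, unique within a dataset.
    obs_time
        Observation time ``X = min(D, C)`` (death or censoring, whichever
        comes first).
    death_observed
        True if the subject died at ``obs_time``.
    nonfatal_times
        Strictly increasing times of nonfatal events, all ``<= obs_time``.
    covariates
        Baseline covariate vector ``z``.
    """

    subject_id: object
    obs_time: float
    death_observed: bool
    nonfatal_times: tuple[float, ...]
    covariates: np.ndarray

    def __post_init__(self):
        if self.obs_time < 0:
            raise ValueError(f"subject {self.subject_id}: negative obs_time")
        times = tuple(float(t) for t in self.nonfatal_times)
        if any(t < 0 for t in times):
            raise ValueError(f"subject {self.subject_id}: negative nonfatal time")
        if any(t > self.obs_time for t in times):
            raise ValueError(
                f"subject {self.subject_id}: nonfatal time exceeds obs_time"
            )
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"subject {self.subject_id}: nonfatal times not strictly increasing"
            )
        z = np.asarray(self.covariates, dtype=float)
        if z.ndim != 1:
            raise ValueError("covariates must be a 1-d vector")
        if np.isnan(z).any():
            raise ValueError(f"subject {self.subject_id}: missing covariate value")
        object.__setattr__(self, "nonfatal_times", times)
        object.__setattr__(self, "covariates", z)

    @property
    def first_nonfatal(self) -> float:
        """Time of first nonfatal event, ``inf`` if none observed."""
        return self.nonfatal_times[0] if self.nonfatal_times else np.inf

    @property
    def outcome_status(self) -> str:
        """'death', 'nonfatal' (alive with event), or 'event_free'."""
        if self.death_observed:
            return "death"
        if self.nonfatal_times:
            return "nonfatal"
        return "event_free"


@dataclass
class Dataset:
    """A collection of :class:`SubjectRecord` with shared covariate names."""

    records: list[SubjectRecord]
    covariate_names: list[str]

    def __post_init__(self):
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        p = len(self.covariate_names)
        for r in self.records:
            if len(r.covariates) != p:
                raise ValueError(
                    f"subject {r.subject_id}: covariate length {len(r.covariates)}"
                    f" != {p}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    @property
    def subject_ids(self) -> list:
        return [r.subject_id for r in self.records]

    def covariate_matrix(self) -> np.ndarray:
        """n x p matrix of covariates in record order."""
        return np.array([r.covariates for r in self.records], dtype=float)

    def outcome_statuses(self) -> list[str]:
        return [r.outcome_status for r in self.records]

    def subset(self, ids: Sequence) -> "Dataset":
        """Dataset restricted to the given subject ids (record order kept)."""
        wanted = set(ids)
        recs = [r for r in self.records if r.subject_id in wanted]
        if len(recs) != len(wanted):
            missing = wanted - {r.subject_id for r in recs}
            raise KeyError(f"unknown subject ids: {sorted(map(str, missing))[:5]}")
        return Dataset(recs, list(self.covariate_names))


@dataclass
class SplitResult:
    """Stratified train/test partition of a :class:`Dataset`."""

    train: Dataset
    test: Dataset
    proportion: float
    strata_counts: pd.DataFrame = field(repr=False)


def read_long_table(source) -> Dataset:
    """Read a long-format event table into a :class:`Dataset`.

    ``source`` is a CSV path or a :class:`pandas.DataFrame` with columns
    ``id``, ``time``, ``status`` and one column per covariate.  Each subject
    must have exactly one terminal row (status 0 or 1) whose time is the
    subject's maximum; status-2 rows are nonfatal events.  Covariates must
    be constant within subject and contain no missing values.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"id", "time", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing required columns {required - set(df.columns)}")
    cov_names = [c for c in df.columns if c not in required]
    bad = set(df["status"].unique()) - {STATUS_CENSOR, STATUS_DEATH, STATUS_NONFATAL}
    if bad:
        raise ValueError(f"unknown status codes: {sorted(bad)}")
    if df[["time"] + cov_names].isna().any().any():
        raise ValueError("missing values in time or covariate columns")

    records = []
    for sid, grp in df.groupby("id", sort=True):
        terminal = grp[grp["status"] != STATUS_NONFATAL]
        if len(terminal) == 0:
            raise ValueError(f"subject {sid}: no terminal (status 0/1) row")
        if len(terminal) > 1:
            raise ValueError(f"subject {sid}: multiple terminal rows")
        t_row = terminal.iloc[0]
        obs_time = float(t_row["time"])
        if obs_time < grp["time"].max():
            raise ValueError(
                f"subject {sid}: nonfatal time exceeds terminal time"
            )
        z = grp[cov_names].to_numpy(dtype=float)
        if len(grp) > 1 and not (z == z[0]).all():
            raise ValueError(f"subject {sid}: covariates not constant within subject")
        nf = np.unique(grp.loc[grp["status"] == STATUS_NONFATAL, "time"].to_numpy())
        records.append(
            SubjectRecord(
                subject_id=sid,
                obs_time=obs_time,
                death_observed=bool(t_row["status"] == STATUS_DEATH),
                nonfatal_times=tuple(float(t) for t in nf),
                covariates=z[0] if len(grp) else np.empty(0),
            )
        )
    return Dataset(records, cov_names)


def write_long_table(data: Dataset, path=None) -> pd.DataFrame:
    """Serialize a :class:`Dataset` back to the long format (inverse of
    :func:`read_long_table`); optionally write CSV to ``path``."""
    rows = []
    for r in data.records:
        for t in r.nonfatal_times:
            rows.append((r.subject_id, t, STATUS_NONFATAL, *r.covariates))
        status = STATUS_DEATH if r.death_observed else STATUS_CENSOR
        rows.append((r.subject_id, r.obs_time, status, *r.covariates))
    df = pd.DataFrame(rows, columns=["id", "time", "status", *data.covariate_names])
    if path is not None:
        df.to_csv(path, index=False)
    return df


def split_train_test(data: Dataset, proportion: float = 0.8,
                     seed: int | None = None) -> SplitResult:
    """Random train/test split stratified by outcome status.

    ``proportion`` is the training fraction.  Strata are the three mutually
    exclusive outcome categories (died; alive with a nonfatal event;
    event-free), so both tiers of the outcome hierarchy stay balanced
    between training and test data.  A stratum with fewer than 2 subjects
    is allocated entirely to the training set with a warning.
    """
    if not 0 < proportion < 1:
        raise ValueError(f"proportion must be in (0,1), got {proportion}")
    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    counts = {}
    statuses = np.array(data.outcome_statuses())
    ids = np.array(data.subject_ids, dtype=object)
    for cat in STATUS_CATEGORIES:
        members = ids[statuses == cat]
        if len(members) == 0:
            continue
        if len(members) < 2:
            warnings.warn(
                f"stratum '{cat}' has {len(members)} subject(s); allocated to train"
            )
            train_ids.extend(members)
            counts[cat] = (len(members), 0)
            continue
        perm = rng.permutation(len(members))
        n_test = int(round(len(members) * (1 - proportion)))
        test_m = members[perm[:n_test]]
        train_m = members[perm[n_test:]]
        train_ids.extend(train_m)
        test_ids.extend(test_m)
        counts[cat] = (len(train_m), len(test_m))
    strata = pd.DataFrame(counts, index=["train", "test"]).T
    return SplitResult(
        train=data.subset(train_ids),
        test=data.subset(test_ids),
        proportion=proportion,
        strata_counts=strata,
    )
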