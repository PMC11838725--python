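import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import winratio as wr

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_record(sid, obs_time, death, nonfatal=(), z=(0.0,)):
    return wr.SubjectRecord(subject_id=sid, obs_time=obs_time,
                            death_observed=death,
                            nonfatal_times=tuple(nonfatal),
                            covariates=np.asarray(z, dtype=float))


@pytest.fixture(scope="session")
def small_dataset():
    """n=60 subjects from the same-effects scenario; enough pairs to fit."""
    return wr.generate_dataset(wr.scenario1(n=60, p=5, seed=17))


@pytest.fixture(scope="session")
def small_pairs(small_dataset):
    return wr.build_pair_set(small_dataset)


@pytest.fixture(scope="session")
def train_dataset():
    """n=150 training-sized dataset used by slower CV/fit tests."""
    return wr.generate_dataset(wr.scenario1(n=150, p=10, seed=23))


@pytest.fixture
def gbc_like_frame():
    """Long-format toy table in the German-breast-cancer layout."""
    return pd.DataFrame(
        {"id": [1, 1, 2, 9],
         "time": [43.836066, 74.819672, 46.557377, 5.0],
         "status": [2, 0, 0, 1],
         "age": [38, 38, 52, 61],
         "size": [18, 18, 20, 25]})
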