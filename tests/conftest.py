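from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from allochrony.synthetic_data import CountsSimConfig, simulate_counts
from allochrony.trial_stats import MatingObservation


def make_obs(strain: str, time, trial_id: str = "t") -> MatingObservation:
    """Mated observation with an exact rational time in hours."""
    return MatingObservation(trial_id, strain, True, Fraction(time).limit_denominator(3))


@pytest.fixture
def trial_csv(tmp_path):
    """Well-formed 3-row trial CSV: two mated, one not."""
    path = tmp_path / "trials.csv"
    path.write_text(
        "trial_id,strain,mated,time_h\n"
        "a1,E,1,1.333333\n"
        "a2,Z,1,4.0\n"
        "a3,E,0,\n"
    )
    return path


@pytest.fixture
def small_counts():
    """Deterministic 100-transcript count matrix with the dropped library."""
    counts, meta, truth = simulate_counts(
        CountsSimConfig(n_transcripts=100, drop_library=True, seed=11)
    )
    return counts, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
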