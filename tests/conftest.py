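"""Shared fixtures: small and paper-scale synthetic experiments."""

import warnings

import numpy as np
import pandas as pd
import pytest

from titplayback import (
    DesignConfig,
    TruthParams,
    build_index_table,
    paper_design,
    sample_schedule,
    simulate_trials,
    summarize_trials,
)
from titplayback.ethogram import trials_from_frame
from titplayback.simulate import PRE_SECONDS, RESPONSE_SECONDS
from titplayback.ethogram import EthogramSeries


def make_series(
    trial_id="t1",
    male_id="m1",
    distance=7.0,
    singing_from=None,
    singing_until=RESPONSE_SECONDS,
    **meta,
) -> EthogramSeries:
    """Construct a simple ethogram series: constant distance, one song bout."""
    singing = np.zeros(RESPONSE_SECONDS, dtype=int)
    if singing_from is not None:
        singing[singing_from - 1 : singing_until] = 1
    dist = np.full(RESPONSE_SECONDS, float(distance))
    return EthogramSeries(
        trial_id=trial_id,
        male_id=male_id,
        species=meta.get("species", "great tit"),
        playback_species=meta.get("playback_species", "great tit"),
        treatment=meta.get("treatment", "conspecific"),
        already_singing=meta.get("already_singing", 0),
        trial_seq=meta.get("trial_seq", 1),
        minutes_after_sunrise=meta.get("minutes_after_sunrise", 60.0),
        pre_distance=np.full(PRE_SECONDS, float(distance)),
        pre_singing=np.zeros(PRE_SECONDS, dtype=int),
        distance=dist,
        singing=singing,
    )


@pytest.fixture(scope="session")
def small_design() -> DesignConfig:
    return DesignConfig(
        territory_counts={"great tit": 4, "blue tit": 4, "marsh tit": 4,
                          "crested tit": 4, "coal tit": 4},
        min_heterospecific_reps=0,
    )


@pytest.fixture(scope="session")
def small_experiment(small_design):
    """Schedule, trial-seconds table and scored index for a 20-male study."""
    schedule = sample_schedule(small_design, seed=11)
    trials = simulate_trials(schedule, TruthParams(), seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        variables = summarize_trials(trials_from_frame(trials))
        index = build_index_table(variables)
    return {"schedule": schedule, "trials": trials, "variables": variables,
            "index": index}


@pytest.fixture(scope="session")
def paper_experiment():
    """One full synthetic experiment at the field study's scale (333 trials)."""
    schedule = sample_schedule(paper_design(), seed=42)
    trials = simulate_trials(schedule, TruthParams(), seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        variables = summarize_trials(trials_from_frame(trials))
        index = build_index_table(variables)
    return {"schedule": schedule, "trials": trials, "variables": variables,
            "index": index}
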