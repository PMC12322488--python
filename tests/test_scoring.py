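"""Scaling, the 0-4 composite score and the within-male-centered index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titplayback import ScalingConfig, build_index_table, compose_index, scale_components


def vars_table(rows):
    defaults = {
        "male_id": "m1", "species": "great tit", "playback_species": "great tit",
        "treatment": "conspecific", "already_singing": 0, "trial_seq": 1,
        "minutes_after_sunrise": 60.0, "min_distance": 10.0,
        "mean_distance_singing": 12.0, "total_singing": 100, "latency": 100,
        "censored_no_song": False, "censored_no_distance": False,
        "flagged_missing": False,
    }
    out = []
    for i, row in enumerate(rows):
        r = dict(defaults, trial_id=f"t{i}", **row)
        out.append(r)
    return pd.DataFrame(out)


def test_worked_example_120_of_480_scales_to_quarter():
    df = vars_table([{"total_singing": 120}, {"total_singing": 0}])
    scored = scale_components(df)
    assert scored.loc[0, "scaled_singing"] == 0.25


def test_censored_latency_scales_to_zero_and_first_second_to_one():
    df = vars_table([{"latency": 480}, {"latency": 1}])
    scored = scale_components(df)
    assert scored.loc[0, "scaled_latency"] == 0.0
    assert scored.loc[1, "scaled_latency"] == 1.0


def test_global_min_distance_scales_to_one():
    df = vars_table(
        [{"min_distance": 3.0}, {"min_distance": 20.0}, {"min_distance": 50.0}]
    )
    scored = scale_components(df)
    assert scored.loc[0, "scaled_min_distance"] == 1.0
    assert scored.loc[2, "scaled_min_distance"] == 0.0


def test_constant_distances_warn_and_score_half():
    df = vars_table([{"min_distance": 5.0}, {"min_distance": 5.0}])
    with pytest.warns(UserWarning, match="no information"):
        scored = scale_components(df)
    assert (scored["scaled_min_distance"] == 0.5).all()


def test_distance_shift_invariance():
    """Adding a constant to every distance leaves min-max scaling unchanged."""
    rows = [{"min_distance": d, "mean_distance_singing": d + 2.0} for d in (2.0, 9.0, 30.0)]
    a = scale_components(vars_table(rows))
    shifted = [
        {"min_distance": d + 7.5, "mean_distance_singing": d + 9.5} for d in (2.0, 9.0, 30.0)
    ]
    b = scale_components(vars_table(shifted))
    np.testing.assert_allclose(
        a["scaled_min_distance"], b["scaled_min_distance"], atol=1e-12
    )
    np.testing.assert_allclose(
        a["scaled_mean_distance_singing"], b["scaled_mean_distance_singing"], atol=1e-12
    )


def test_per_species_scaling_basis():
    rows = [
        {"species": "great tit", "min_distance": 2.0},
        {"species": "great tit", "min_distance": 10.0},
        {"species": "coal tit", "min_distance": 20.0},
        {"species": "coal tit", "min_distance": 40.0},
    ]
    scored = scale_components(vars_table(rows), ScalingConfig(distance_basis="per_species"))
    assert scored.loc[0, "scaled_min_distance"] == 1.0
    assert scored.loc[2, "scaled_min_distance"] == 1.0


def test_strongest_trial_composes_to_four():
    """All four components at their strongest value give a raw score of 4."""
    rows = [
        {"total_singing": 480, "latency": 1, "min_distance": 0.0,
         "mean_distance_singing": 0.0},
        {"total_singing": 0, "latency": 480, "min_distance": 50.0,
         "mean_distance_singing": 50.0, "male_id": "m2"},
    ]
    with pytest.warns(UserWarning):
        out = build_index_table(vars_table(rows))
    assert out.loc[0, "raw_score"] == pytest.approx(4.0)
    assert out.loc[1, "raw_score"] == pytest.approx(0.0)


def test_centering_arithmetic():
    df = vars_table([{}, {}, {}])
    df["scaled_singing"] = [0.25, 0.5, 0.75]
    df["scaled_min_distance"] = [0.25, 0.5, 0.75]
    df["scaled_mean_distance_singing"] = [0.25, 0.5, 0.75]
    df["scaled_latency"] = [0.25, 0.5, 0.75]
    out = compose_index(df)
    np.testing.assert_allclose(out["raw_score"], [1.0, 2.0, 3.0])
    np.testing.assert_allclose(out["aggression_index"], [-1.0, 0.0, 1.0])


def test_single_trial_male_warns_and_centers_to_zero():
    df = vars_table([{"male_id": "solo"}])
    for c in ("scaled_singing", "scaled_min_distance",
              "scaled_mean_distance_singing", "scaled_latency"):
        df[c] = 0.6
    with pytest.warns(UserWarning, match="single trial"):
        out = compose_index(df)
    assert out.loc[0, "aggression_index"] == 0.0


@settings(max_examples=25, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=480), min_size=2, max_size=8),
       st.integers(min_value=0, max_value=2**31 - 1))
def test_index_sums_to_zero_within_male(sing, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for i, ts in enumerate(sing):
        rows.append(
            {"male_id": f"m{i % 2}", "total_singing": ts,
             "latency": int(rng.integers(1, 481)),
             "min_distance": float(rng.uniform(0, 50)),
             "mean_distance_singing": float(rng.uniform(0, 50))}
        )
    import warnings as w
    with w.catch_warnings():
        w.simplefilter("ignore")
        out = build_index_table(vars_table(rows))
    sums = out.groupby("male_id")["aggression_index"].sum()
    assert (sums.abs() < 1e-9).all()
    # order preservation within male
    for _, grp in out.groupby("male_id"):
        assert (
            grp["raw_score"].rank(method="first")
            == grp["aggression_index"].rank(method="first")
        ).all()


def test_paper_scale_index_distribution(paper_experiment):
    """At the field scale the index is near mean-zero with full support."""
    idx = paper_experiment["index"]
    assert abs(idx["aggression_index"].mean()) < 0.05
    assert idx["raw_score"].between(0, 4).all()
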