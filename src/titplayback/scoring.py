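"""Composite aggression score and within-male-centered aggression index.

Each of the four trial variables is mapped to a [0, 1] scale with 1 = the
strongest aggressive response:

* total singing time has a direct relation to aggression and is scaled by
  the fixed 480 s window (120 s of song -> 0.25);
* latency, minimum distance and mean singing distance have an inverse
  relation: they are scaled to [0, 1] and flipped (1 - scaled value).
  Latency uses its theoretical span [1, 480] s (song in second 1 -> 1,
  censored 480 -> 0); distances have no theoretical bound and are min-max
  scaled over the dataset (globally by default, per species or over fixed
  bounds by configuration).

The four components sum to a raw score in [0, 4]; centering raw scores
within each territorial male yields the aggression index, which isolates
within-individual variation in response to the different playback stimuli.
The four raw variables are also centered within male for the per-variable
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import RESPONSE_SECONDS

SCALED_COLUMNS = [
    "scaled_singing",
    "scaled_min_distance",
    "scaled_mean_distance_singing",
    "scaled_latency",
]

CENTERED_VARIABLE_COLUMNS = [
    "centered_min_distance",
    "centered_mean_distance_singing",
    "centered_total_singing",
    "centered_latency",
]


@dataclass
class ScalingConfig:
    """How the inverse-relation distance variables are min-max scaled.

    distance_basis
        ``"global"`` (default): one min-max over all trials in the dataset;
        ``"per_species"``: min-max within each focal species;
        ``"fixed"``: use ``fixed_bounds`` (e.g. 0 to the maximum visible
        distance) for both distance variables.
    """

    distance_basis: str = "global"
    fixed_bounds: tuple[float, float] = (0.0, 50.0)

    def __post_init__(self) -> None:
        if self.distance_basis not in ("global", "per_species", "fixed"):
            raise ValueError(f"unknown distance_basis {self.distance_basis!r}")


def _scale_inverse(values: np.ndarray, lo: float, hi: float, what: str) -> np.ndarray:
    if hi == lo:
        warnings.warn(
            f"all {what} values identical ({lo}); component carries no "
            "information and is set to 0.5", stacklevel=3
        )
        return np.full_like(values, 0.5, dtype=float)
    return 1.0 - (values - lo) / (hi - lo)


def scale_components(
    variables: pd.DataFrame, config: ScalingConfig | None = None
) -> pd.DataFrame:
    """Add the four scaled [0, 1] components to a variables table."""
    config = ScalingConfig() if config is None else config
    if len(variables) < 1:
        raise ValueError("need at least one trial to scale")
    df = variables.copy()
    df["scaled_singing"] = df["total_singing"].to_numpy(float) / RESPONSE_SECONDS
    df["scaled_latency"] = (RESPONSE_SECONDS - df["latency"].to_numpy(float)) / (
        RESPONSE_SECONDS - 1
    )

    for col, out in (
        ("min_distance", "scaled_min_distance"),
        ("mean_distance_singing", "scaled_mean_distance_singing"),
    ):
        vals = df[col].to_numpy(float)
        if config.distance_basis == "fixed":
            lo, hi = config.fixed_bounds
            df[out] = np.clip(_scale_inverse(vals, lo, hi, col), 0.0, 1.0)
        elif config.distance_basis == "per_species":
            scaled = np.empty(len(df))
            for sp, idx in df.groupby("species").groups.items():
                sub = df.loc[idx, col].to_numpy(float)
                scaled[df.index.get_indexer(idx)] = _scale_inverse(
                    sub, sub.min(), sub.max(), f"{col} ({sp})"
                )
            df[out] = scaled
        else:
            df[out] = _scale_inverse(vals, vals.min(), vals.max(), col)
    return df


def compose_index(scored: pd.DataFrame) -> pd.DataFrame:
    """Sum the scaled components and center within territorial male.

    Adds ``raw_score`` (0-4), ``aggression_index`` (raw score centered within
    male) and the per-variable within-male centered responses.
    """
    missing = [c for c in SCALED_COLUMNS if c not in scored.columns]
    if missing:
        raise ValueError(f"scored table missing scaled columns {missing}")
    df = scored.copy()
    df["raw_score"] = df[SCALED_COLUMNS].sum(axis=1)

    singles = df.groupby("male_id")["trial_id"].transform("size") == 1
    if singles.any():
        warnings.warn(
            f"{int(singles.sum())} male(s) have a single trial; their centered "
            "index is 0 by construction", stacklevel=2
        )
    df["aggression_index"] = df["raw_score"] - df.groupby("male_id")["raw_score"].transform(
        "mean"
    )
    for raw, centered in (
        ("min_distance", "centered_min_distance"),
        ("mean_distance_singing", "centered_mean_distance_singing"),
        ("total_singing", "centered_total_singing"),
        ("latency", "centered_latency"),
    ):
        df[centered] = df[raw] - df.groupby("male_id")[raw].transform("mean")
    return df


def build_index_table(
    variables: pd.DataFrame, config: ScalingConfig | None = None
) -> pd.DataFrame:
    """variables table -> fully scored index table (scale + compose)."""
    return compose_index(scale_components(variables, config))
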