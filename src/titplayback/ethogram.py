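"""Per-second focal-observation records and their trial-level reduction.

Each playback trial is a 9-minute focal sample: a 60 s pre-playback window
(used only to record whether the male was already singing) followed by a
480 s response window (4 min of stimulus broadcast + 4 min of observation).
The four trial-level aggression variables are computed on the response
window only:

* minimum distance to the speaker (m),
* mean distance to the speaker during singing (m),
* total time spent singing (s),
* latency of the vocal response (s, 1-based from playback onset).

Censoring at the weakest-response bound keeps each variable's ordering
semantics when a bird never sings (latency = 480 s, mean singing distance =
the maximum visible distance) or is never localized (minimum distance = the
maximum visible distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PRE_SECONDS, RESPONSE_SECONDS

#: Default cap used for censoring (speakers were audible and the bird
#: observable only within a bounded radius; configurable).
DEFAULT_MAX_VISIBLE_DISTANCE = 50.0

#: A trial with more than this fraction of missing response seconds is
#: flagged (not dropped).
MISSING_FLAG_FRACTION = 0.2

VARIABLE_COLUMNS = [
    "trial_id", "male_id", "species", "playback_species", "treatment",
    "already_singing", "trial_seq", "minutes_after_sunrise",
    "min_distance", "mean_distance_singing", "total_singing", "latency",
    "censored_no_song", "censored_no_distance", "flagged_missing",
]


@dataclass
class EthogramSeries:
    """One trial's per-second record (distances in m, singing 0/1).

    Missing single seconds (observer lost the bird) are NaN distances; the
    singing channel has no missing values.
    """

    trial_id: str
    male_id: str
    species: str
    playback_species: str
    treatment: str
    already_singing: int
    trial_seq: int
    minutes_after_sunrise: float
    pre_distance: np.ndarray
    pre_singing: np.ndarray
    distance: np.ndarray
    singing: np.ndarray

    def validate(self) -> None:
        if len(self.distance) != RESPONSE_SECONDS or len(self.singing) != RESPONSE_SECONDS:
            raise ValueError(
                f"trial {self.trial_id!r}: response window must be exactly "
                f"{RESPONSE_SECONDS} s, got {len(self.distance)}"
            )
        if len(self.pre_distance) != PRE_SECONDS or len(self.pre_singing) != PRE_SECONDS:
            raise ValueError(
                f"trial {self.trial_id!r}: pre window must be exactly {PRE_SECONDS} s, "
                f"got {len(self.pre_distance)}"
            )
        for name, sing in (("pre", self.pre_singing), ("response", self.singing)):
            if not np.isin(sing, (0, 1)).all():
                raise ValueError(
                    f"trial {self.trial_id!r}: singing outside {{0,1}} in {name} window"
                )
        for name, dist in (("pre", self.pre_distance), ("response", self.distance)):
            finite = dist[~np.isnan(dist)]
            if (finite < 0).any():
                raise ValueError(
                    f"trial {self.trial_id!r}: negative distance in {name} window"
                )


@dataclass
class AggressionVariables:
    """The four trial-level summaries plus censoring bookkeeping."""

    min_distance: float
    mean_distance_singing: float
    total_singing: int
    latency: int
    censored_no_song: bool = False
    censored_no_distance: bool = False
    flagged_missing: bool = False


def summarize_trial(
    series: EthogramSeries,
    max_visible_distance: float = DEFAULT_MAX_VISIBLE_DISTANCE,
    missing_flag_fraction: float = MISSING_FLAG_FRACTION,
) -> AggressionVariables:
    """Reduce one trial to the four aggression variables.

    Latency is the 1-based index of the first singing second of the response
    window (a bird singing in second 1 has latency 1).  The pre-window never
    contributes to any variable.
    """
    series.validate()
    singing = np.asarray(series.singing)
    dist = np.asarray(series.distance, dtype=float)
    observed = ~np.isnan(dist)

    total_singing = int(singing.sum())
    sang = total_singing > 0
    censored_no_song = not sang
    latency = int(np.argmax(singing == 1) + 1) if sang else RESPONSE_SECONDS

    censored_no_distance = not observed.any()
    min_distance = float(dist[observed].min()) if observed.any() else float(max_visible_distance)

    sing_obs = observed & (singing == 1)
    if sing_obs.any():
        mean_distance_singing = float(dist[sing_obs].mean())
    else:
        mean_distance_singing = float(max_visible_distance)

    flagged = (1.0 - observed.mean()) > missing_flag_fraction
    return AggressionVariables(
        min_distance=min_distance,
        mean_distance_singing=mean_distance_singing,
        total_singing=total_singing,
        latency=latency,
        censored_no_song=censored_no_song,
        censored_no_distance=censored_no_distance,
        flagged_missing=bool(flagged),
    )


def _series_from_group(trial_id: str, grp: pd.DataFrame) -> EthogramSeries:
    dup = grp.duplicated(subset=["phase", "t_sec"])
    if dup.any():
        row = grp.iloc[int(np.argmax(dup.to_numpy()))]
        raise ValueError(
            f"trial {trial_id!r}: duplicate record at phase={row['phase']!r} "
            f"t_sec={int(row['t_sec'])}"
        )
    bad = ~grp["singing"].isin([0, 1])
    if bad.any():
        row = grp.iloc[int(np.argmax(bad.to_numpy()))]
        raise ValueError(
            f"trial {trial_id!r}: singing value {row['singing']!r} outside {{0,1}} "
            f"at t_sec={int(row['t_sec'])}"
        )
    pre = grp[grp["phase"] == "pre"].sort_values("t_sec")
    resp = grp[grp["phase"] == "response"].sort_values("t_sec")
    meta = grp.iloc[0]
    series = EthogramSeries(
        trial_id=str(trial_id),
        male_id=str(meta["male_id"]),
        species=str(meta["species"]),
        playback_species=str(meta["playback_species"]),
        treatment=str(meta["treatment"]),
        already_singing=int(meta["already_singing"]),
        trial_seq=int(meta["trial_seq"]),
        minutes_after_sunrise=float(meta["minutes_after_sunrise"]),
        pre_distance=pre["distance_m"].to_numpy(dtype=float),
        pre_singing=pre["singing"].to_numpy(),
        distance=resp["distance_m"].to_numpy(dtype=float),
        singing=resp["singing"].to_numpy(),
    )
    series.validate()
    return series


def trials_from_frame(trials: pd.DataFrame) -> list[EthogramSeries]:
    """Split a tidy trial-second frame into validated per-trial series."""
    required = {"trial_id", "phase", "t_sec", "distance_m", "singing"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials table missing columns {sorted(missing)}")
    return [
        _series_from_group(tid, grp) for tid, grp in trials.groupby("trial_id", sort=True)
    ]


def read_trials(path) -> list[EthogramSeries]:
    """Read trials.csv (one row per trial-second) into validated series."""
    return trials_from_frame(pd.read_csv(path))


def summarize_trials(
    series_list: list[EthogramSeries],
    max_visible_distance: float = DEFAULT_MAX_VISIBLE_DISTANCE,
) -> pd.DataFrame:
    """Variables table (one row per trial) for a list of series."""
    rows = []
    for s in series_list:
        v = summarize_trial(s, max_visible_distance=max_visible_distance)
        rows.append(
            {
                "trial_id": s.trial_id,
                "male_id": s.male_id,
                "species": s.species,
                "playback_species": s.playback_species,
                "treatment": s.treatment,
                "already_singing": s.already_singing,
                "trial_seq": s.trial_seq,
                "minutes_after_sunrise": s.minutes_after_sunrise,
                "min_distance": v.min_distance,
                "mean_distance_singing": v.mean_distance_singing,
                "total_singing": v.total_singing,
                "latency": v.latency,
                "censored_no_song": v.censored_no_song,
                "censored_no_distance": v.censored_no_distance,
                "flagged_missing": v.flagged_missing,
            }
        )
    df = pd.DataFrame(rows, columns=VARIABLE_COLUMNS)
    n_flagged = int(df["flagged_missing"].sum())
    if n_flagged:
        warnings.warn(
            f"{n_flagged} trial(s) have more than "
            f"{MISSING_FLAG_FRACTION:.0%} missing response seconds", stacklevel=2
        )
    return df
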