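"""Synthetic playback trials with known ground truth.

Generation is two-layer:

1. a latent trial-level aggression score on the 0-4 scale of the composite
   index: ``a = grand_mean + effect(habitat group, treatment)
   + beta_singing * already_singing + beta_seq * z(trial_seq)
   + beta_minutes * z(minutes after sunrise) + u_male + v_playback + eps``
   with Gaussian random intercepts and residual;

2. a behaviour renderer that maps ``a`` through monotone link functions to a
   per-second ethogram (60 s pre-window + 480 s response window): higher
   latent aggression gives more singing seconds, an earlier song onset and a
   closer approach to the speaker.

The links are normalized logistics over the index's 0-4 support, near-linear
in the middle of the scale, so that the recomputed composite score tracks the
latent score approximately one-to-one and treatment contrasts survive the
render -> summarize -> scale round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from ._rng import derive_seed
from .species import (
    BROADLEAF,
    CONIFER,
    CONSPECIFIC,
    EXTRA_HABITAT,
    INTRA_HABITAT,
    SONG_FEATURES,
    SpeciesSpec,
    default_species_table,
    habitat_group_map,
)

PRE_SECONDS = 60
RESPONSE_SECONDS = 480

TRIALS_COLUMNS = [
    "trial_id", "male_id", "species", "playback_species", "treatment",
    "already_singing", "trial_seq", "minutes_after_sunrise",
    "phase", "t_sec", "distance_m", "singing",
]


@dataclass
class TruthParams:
    """Generative ground truth for one synthetic experiment.

    Treatment effects are per (habitat group, treatment) in index units on
    the 0-4 composite scale; the default pattern mirrors the study's
    qualitative finding: broadleaf species grade their response
    (conspecific > intra-habitat > extra-habitat, steps of 1.2 and 0.7 index
    units) while conifer species do not discriminate between heterospecifics.
    """

    grand_mean: float = 1.0
    treatment_effects_by_group: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            (BROADLEAF, CONSPECIFIC): 1.9,
            (BROADLEAF, INTRA_HABITAT): 0.7,
            (BROADLEAF, EXTRA_HABITAT): 0.0,
            (CONIFER, CONSPECIFIC): 2.0,
            (CONIFER, INTRA_HABITAT): 0.0,
            (CONIFER, EXTRA_HABITAT): 0.0,
        }
    )
    beta_already_singing: float = 0.4
    beta_trial_seq: float = -0.05
    beta_minutes: float = 0.02
    sd_male: float = 0.4
    sd_playback_species: float = 0.05
    sd_residual: float = 0.75
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for sd in (self.sd_male, self.sd_playback_species, self.sd_residual):
            if sd < 0:
                raise ValueError("random-effect SDs must be nonnegative")
        keys = set(self.treatment_effects_by_group)
        expected = {
            (g, t)
            for g in (BROADLEAF, CONIFER)
            for t in (CONSPECIFIC, INTRA_HABITAT, EXTRA_HABITAT)
        }
        if keys != expected:
            raise ValueError(
                "treatment_effects_by_group must cover exactly 2 groups x 3 treatments; "
                f"missing {sorted(expected - keys)}, unexpected {sorted(keys - expected)}"
            )


def null_truth(**overrides) -> TruthParams:
    """Truth with all treatment effects zero (for calibration studies)."""
    effects = {
        (g, t): 0.0
        for g in (BROADLEAF, CONIFER)
        for t in (CONSPECIFIC, INTRA_HABITAT, EXTRA_HABITAT)
    }
    return TruthParams(treatment_effects_by_group=effects, **overrides)


@dataclass
class RendererConfig:
    """Constants of the latent-score -> behaviour renderer.

    ``link_center``/``link_width`` parameterize the normalized logistic link
    g(a) = (expit((a-c)/w) - expit(-c/w)) / (expit((4-c)/w) - expit(-c/w)),
    clipped to [0, 1]: the common monotone map from the latent 0-4 score to
    each behavioural fraction (singing fraction, onset earliness, approach
    closeness).  Noise SDs are on the fraction scale (components) and in
    meters (second-to-second distance jitter, AR(1) with coefficient
    ``distance_ar``).  With all noise SDs at 0 the renderer is a
    deterministic function of the latent score.
    """

    max_visible_distance: float = 50.0
    link_center: float = 2.0
    link_width: float = 2.0
    component_noise_sd: float = 0.04
    distance_jitter_sd: float = 1.5
    distance_ar: float = 0.8
    round_distance: bool = True


def latent_link(a: np.ndarray, renderer: RendererConfig | None = None) -> np.ndarray:
    """Monotone link from the latent 0-4 score to a [0, 1] behaviour fraction."""
    r = RendererConfig() if renderer is None else renderer
    lo = expit((0.0 - r.link_center) / r.link_width)
    hi = expit((4.0 - r.link_center) / r.link_width)
    g = (expit((np.asarray(a, dtype=float) - r.link_center) / r.link_width) - lo) / (hi - lo)
    return np.clip(g, 0.0, 1.0)


def latent_scores(schedule: pd.DataFrame, truth: TruthParams, seed: int,
                  species_table: list[SpeciesSpec] | None = None) -> pd.DataFrame:
    """Latent trial aggression scores plus the realized random effects."""
    groups = habitat_group_map(species_table)
    rng = np.random.default_rng(derive_seed(seed, "latent"))
    sched = schedule.reset_index(drop=True)
    n = len(sched)

    def zscore(x: pd.Series) -> np.ndarray:
        v = x.to_numpy(dtype=float)
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    males = sched["male_id"].unique()
    plays = sched["playback_species"].unique()
    u = dict(zip(males, rng.normal(0.0, truth.sd_male, len(males))))
    v = dict(zip(plays, rng.normal(0.0, truth.sd_playback_species, len(plays))))
    eps = rng.normal(0.0, truth.sd_residual, n)

    eff = np.array(
        [
            truth.treatment_effects_by_group[(groups[s], t)]
            for s, t in zip(sched["species"], sched["treatment"])
        ]
    )
    a = (
        truth.grand_mean
        + eff
        + truth.beta_already_singing * sched["already_singing"].to_numpy(float)
        + truth.beta_trial_seq * zscore(sched["trial_seq"])
        + truth.beta_minutes * zscore(sched["minutes_after_sunrise"])
        + np.array([u[m] for m in sched["male_id"]])
        + np.array([v[p] for p in sched["playback_species"]])
        + eps
    )
    out = sched.copy()
    out["latent_score"] = a
    out["u_male"] = [u[m] for m in sched["male_id"]]
    out["v_playback"] = [v[p] for p in sched["playback_species"]]
    return out


def simulate_trials(
    schedule: pd.DataFrame,
    truth: TruthParams,
    seed: int | None = None,
    renderer: RendererConfig | None = None,
    species_table: list[SpeciesSpec] | None = None,
    return_latent: bool = False,
):
    """Render per-second ethograms for every trial in a schedule.

    Returns a tidy frame with one row per trial-second (``TRIALS_COLUMNS``),
    optionally together with the latent-score frame.

    Rendering of one trial, given the latent score ``a`` and the link g:

    * song onset (latency) ``L = 480 - round(479 * s_lat)`` seconds,
      ``s_lat = g + noise`` (higher score, earlier onset);
    * a contiguous song bout of ``round(480 * s_sing)`` seconds from ``L``,
      truncated at the window end (so realized singing time is
      ``min`` of the two draws at saturation);
    * distance: mean level ``(1 - s_dist) * max_visible_distance`` with AR(1)
      jitter, clipped to [0, max_visible_distance] and rounded to the meter,
      emulating field distance estimation.
    """
    seed = truth.rng_seed if seed is None else seed
    r = RendererConfig() if renderer is None else renderer
    lat = latent_scores(schedule, truth, seed, species_table)
    n = len(lat)
    rng = np.random.default_rng(derive_seed(seed, "render"))

    g = latent_link(lat["latent_score"].to_numpy(), r)

    def noisy(gvals: np.ndarray) -> np.ndarray:
        if r.component_noise_sd == 0:
            return gvals.copy()
        return np.clip(gvals + rng.normal(0.0, r.component_noise_sd, n), 0.0, 1.0)

    s_sing, s_lat, s_dist = noisy(g), noisy(g), noisy(g)

    latency = (RESPONSE_SECONDS - np.rint((RESPONSE_SECONDS - 1) * s_lat)).astype(int)
    bout = np.rint(RESPONSE_SECONDS * s_sing).astype(int)

    t = np.arange(1, RESPONSE_SECONDS + 1)
    singing = (
        (t[None, :] >= latency[:, None])
        & (t[None, :] <= (latency + bout - 1)[:, None])
        & (bout[:, None] > 0)
    ).astype(np.int8)

    total_secs = PRE_SECONDS + RESPONSE_SECONDS
    mu = (1.0 - s_dist) * r.max_visible_distance
    if r.distance_jitter_sd > 0:
        white = rng.normal(0.0, r.distance_jitter_sd, (n, total_secs))
        jitter = lfilter([1.0], [1.0, -r.distance_ar], white, axis=1)
    else:
        jitter = np.zeros((n, total_secs))
    distance = np.clip(mu[:, None] + jitter, 0.0, r.max_visible_distance)
    if r.round_distance:
        distance = np.rint(distance)

    pre_singing = np.repeat(
        lat["already_singing"].to_numpy(np.int8)[:, None], PRE_SECONDS, axis=1
    )

    phase = np.array(["pre"] * PRE_SECONDS + ["response"] * RESPONSE_SECONDS)
    t_sec = np.concatenate([np.arange(1, PRE_SECONDS + 1), t])
    sing_all = np.concatenate([pre_singing, singing], axis=1)

    meta_cols = [
        "trial_id", "male_id", "species", "playback_species", "treatment",
        "already_singing", "trial_seq", "minutes_after_sunrise",
    ]
    out = lat.loc[lat.index.repeat(total_secs), meta_cols].reset_index(drop=True)
    out["phase"] = np.tile(phase, n)
    out["t_sec"] = np.tile(t_sec, n)
    out["distance_m"] = distance.ravel()
    out["singing"] = sing_all.ravel()
    out = out[TRIALS_COLUMNS]
    if return_latent:
        return out, lat
    return out


def simulate_song_exemplars(
    species_table: list[SpeciesSpec] | None = None,
    n_exemplars: int = 3,
    syllables_per_exemplar: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Syllable-level acoustic feature sequences per song exemplar.

    Each exemplar is a sequence of syllable feature vectors drawn i.i.d.
    around the species' song profile, so within-species exemplars are closer
    (in feature space, hence under DTW) than between-species ones by
    construction.
    """
    if n_exemplars < 1:
        raise ValueError("n_exemplars must be >= 1")
    table = default_species_table() if species_table is None else species_table
    rng = np.random.default_rng(derive_seed(seed, "songs"))
    rows = []
    for sp in table:
        mean = np.array(sp.song_profile_mean)
        sd = np.array(sp.song_profile_sd)
        for e in range(1, n_exemplars + 1):
            feats = rng.normal(mean, sd, size=(syllables_per_exemplar, len(mean)))
            for i, f in enumerate(feats, start=1):
                row = {"species": sp.species_id, "exemplar_id": f"{sp.species_id}-x{e}",
                       "syllable_idx": i}
                row.update({name: float(v) for name, v in zip(SONG_FEATURES, f)})
                rows.append(row)
    return pd.DataFrame(rows)


def simulate_territory_points(
    schedule: pd.DataFrame,
    seed: int = 0,
    n_points: int = 20,
    territory_spacing: float = 150.0,
    spread: float = 35.0,
) -> pd.DataFrame:
    """Observation point clouds for every male in a schedule.

    Territory centers sit on a jittered square grid (meters, planar) spaced
    ``territory_spacing`` apart; observation points scatter isotropically
    around each center with SD ``spread``.
    """
    rng = np.random.default_rng(derive_seed(seed, "territories"))
    males = schedule[["male_id", "species"]].drop_duplicates().reset_index(drop=True)
    k = int(np.ceil(np.sqrt(len(males))))
    order = rng.permutation(len(males))
    rows = []
    for slot, i in enumerate(order):
        cx = (slot % k) * territory_spacing + rng.normal(0, territory_spacing / 8)
        cy = (slot // k) * territory_spacing + rng.normal(0, territory_spacing / 8)
        pts = rng.normal([cx, cy], spread, size=(n_points, 2))
        for x, y in pts:
            rows.append(
                {
                    "male_id": males.loc[i, "male_id"],
                    "species": males.loc[i, "species"],
                    "x": float(np.round(x, 1)),
                    "y": float(np.round(y, 1)),
                }
            )
    return pd.DataFrame(rows)


def truth_to_dict(truth: TruthParams) -> dict:
    """YAML-serializable form of TruthParams (tuple keys flattened)."""
    d = asdict(truth)
    d["treatment_effects_by_group"] = {
        f"{g}:{t}": v for (g, t), v in truth.treatment_effects_by_group.items()
    }
    return d


def truth_from_dict(d: dict) -> TruthParams:
    d = dict(d)
    eff = {}
    for key, v in d.pop("treatment_effects_by_group").items():
        g, t = key.split(":")
        eff[(g, t)] = float(v)
    return TruthParams(treatment_effects_by_group=eff, **d)
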