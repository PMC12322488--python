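"""Study species and playback-treatment classification.

The guild comprises five sympatric tit (Paridae) species partitioned by main
breeding habitat: great, blue and marsh tit in broadleaf woodland; crested
and coal tit in conifer woodland.  A playback trial's treatment level is a
pure function of the focal species, the playback species and this habitat
map: conspecific (same species), heterospecific intra-habitat (different
species, same habitat group) or heterospecific extra-habitat (different
habitat group).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BROADLEAF = "broadleaf"
CONIFER = "conifer"

CONSPECIFIC = "conspecific"
INTRA_HABITAT = "intra_habitat"
EXTRA_HABITAT = "extra_habitat"

#: Treatment factor levels in the conventional strongest-to-weakest order.
TREATMENT_LEVELS = (CONSPECIFIC, INTRA_HABITAT, EXTRA_HABITAT)

#: Canonical species ordering used for matrices and tables.
SPECIES_ORDER = ("great tit", "blue tit", "marsh tit", "crested tit", "coal tit")

#: Acoustic features carried by syllable-level song tables.
SONG_FEATURES = (
    "duration_s",
    "peak_freq_khz",
    "min_freq_khz",
    "max_freq_khz",
    "bandwidth_khz",
)


@dataclass(frozen=True)
class SpeciesSpec:
    """One guild member: habitat group, body mass and a song-feature profile.

    ``body_mass`` (g) and the song profile are configurable placeholders used
    by the synthetic generator and the species-pair matrices; they only need
    to be ordered plausibly, not to match any ringing-databank value.
    """

    species_id: str
    habitat_group: str
    body_mass: float
    song_profile_mean: tuple[float, ...]
    song_profile_sd: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.habitat_group not in (BROADLEAF, CONIFER):
            raise ValueError(
                f"unknown habitat group {self.habitat_group!r} for {self.species_id!r}"
            )
        if not np.isfinite(self.body_mass) or self.body_mass <= 0:
            raise ValueError(f"body mass must be finite and positive for {self.species_id!r}")
        if len(self.song_profile_mean) != len(self.song_profile_sd):
            raise ValueError("song profile mean and sd must have equal length")


def default_species_table() -> list[SpeciesSpec]:
    """The five study species with the fixed habitat-group map.

    Body masses are placeholders ordered great > coal ~ blue > marsh >
    crested so that the mass-difference matrix is non-degenerate.  Song
    profiles are placeholders too (syllable duration, peak, min and max
    frequency, bandwidth): each species is offset along one feature axis so
    that every species pair sits at the same profile distance (a regular
    simplex).  That keeps within-species song variation smaller than
    between-species variation while making song similarity orthogonal to
    the habitat grouping by construction, so the synthetic null carries no
    structural song-aggression association.
    """
    return [
        SpeciesSpec(
            "great tit", BROADLEAF, 18.0,
            (0.36, 4.8, 2.95, 6.6, 3.15), (0.03, 0.25, 0.20, 0.30, 0.25),
        ),
        SpeciesSpec(
            "blue tit", BROADLEAF, 10.7,
            (0.16, 6.8, 2.95, 6.6, 3.15), (0.02, 0.35, 0.25, 0.40, 0.35),
        ),
        SpeciesSpec(
            "marsh tit", BROADLEAF, 10.2,
            (0.16, 4.8, 4.20, 6.6, 3.15), (0.02, 0.30, 0.25, 0.35, 0.30),
        ),
        SpeciesSpec(
            "crested tit", CONIFER, 9.8,
            (0.16, 4.8, 2.95, 8.6, 3.15), (0.02, 0.30, 0.20, 0.40, 0.35),
        ),
        SpeciesSpec(
            "coal tit", CONIFER, 10.9,
            (0.16, 4.8, 2.95, 6.6, 4.90), (0.02, 0.30, 0.25, 0.35, 0.30),
        ),
    ]


def species_map(table: list[SpeciesSpec] | None = None) -> dict[str, SpeciesSpec]:
    table = default_species_table() if table is None else table
    return {sp.species_id: sp for sp in table}


def habitat_group_map(table: list[SpeciesSpec] | None = None) -> dict[str, str]:
    return {sid: sp.habitat_group for sid, sp in species_map(table).items()}


def classify_treatment(
    focal_species: str,
    playback_species: str,
    species_table: list[SpeciesSpec] | None = None,
) -> str:
    """Classify a (focal, playback) pair into the three-level treatment factor."""
    groups = habitat_group_map(species_table)
    for label in (focal_species, playback_species):
        if label not in groups:
            raise KeyError(f"unknown species label {label!r}")
    if focal_species == playback_species:
        return CONSPECIFIC
    if groups[focal_species] == groups[playback_species]:
        return INTRA_HABITAT
    return EXTRA_HABITAT
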