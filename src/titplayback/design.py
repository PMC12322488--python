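"""Trial-schedule generation for the playback experiment.

A schedule assigns each territorial male a set of playback stimuli subject to
the experiment's design rules: at least one conspecific and two heterospecific
stimuli per male, at most four stimuli per male, a minimum number of
experiment-wide repetitions of every focal x playback heterospecific pair, no
male tested twice on the same day, and a minimum gap in days between a male's
consecutive trials.

The default configuration reproduces the study's printed trial-allocation
grid (101 territories, 333 trials: 103 conspecific, 97 intra-habitat, 133
extra-habitat); arbitrary smaller designs are supported for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .species import (
    SPECIES_ORDER,
    SpeciesSpec,
    classify_treatment,
    default_species_table,
    habitat_group_map,
)

#: Territories per species in the field experiment (sums to 101).
DEFAULT_TERRITORY_COUNTS = {
    "great tit": 21,
    "blue tit": 21,
    "marsh tit": 21,
    "crested tit": 20,
    "coal tit": 18,
}

#: Default focal x playback trial-allocation grid (rows = focal species,
#: columns = playback species, order as SPECIES_ORDER).  Row sums give the
#: per-species trial totals (70, 68, 71, 68, 56; grand total 333) and the
#: diagonal the conspecific counts (103).
DEFAULT_TRIAL_TARGETS = np.array(
    [
        [21, 12, 11, 12, 14],
        [14, 21, 12, 9, 12],
        [11, 12, 23, 15, 10],
        [11, 11, 12, 20, 14],
        [9, 10, 8, 11, 18],
    ],
    dtype=int,
)

SCHEDULE_COLUMNS = [
    "trial_id",
    "male_id",
    "species",
    "playback_species",
    "treatment",
    "trial_seq",
    "day",
    "minutes_after_sunrise",
    "already_singing",
]


class InfeasibleDesignError(ValueError):
    """Raised when the requested design constraints cannot all be satisfied."""


@dataclass
class DesignConfig:
    """Design parameters for schedule generation.

    territory_counts
        Males (= territories) per focal species.
    trial_targets
        Optional focal x playback count grid to reproduce exactly (species in
        ``SPECIES_ORDER`` restricted to the configured species).  When None,
        each male receives 1 conspecific plus ``n_heterospecific_per_male``
        heterospecific stimuli, with ``n_males_with_extra`` random males
        receiving one extra heterospecific stimulus.
    min_heterospecific_reps
        Experiment-wide minimum repetitions of each focal x playback
        heterospecific combination.
    min_gap_days
        Minimum number of days between a male's consecutive trials.
    """

    territory_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TERRITORY_COUNTS)
    )
    trial_targets: np.ndarray | None = None
    n_heterospecific_per_male: int = 2
    n_males_with_extra: int = 0
    max_stimuli_per_male: int = 4
    balance_treatments_within_male: bool = True
    min_heterospecific_reps: int = 0
    min_gap_days: int = 2
    n_days: int = 31
    minutes_after_sunrise_range: tuple[float, float] = (0.0, 270.0)
    p_already_singing: float = 0.3


def paper_design() -> DesignConfig:
    """The configuration matching the field experiment's bookkeeping."""
    return DesignConfig(
        territory_counts=dict(DEFAULT_TERRITORY_COUNTS),
        trial_targets=DEFAULT_TRIAL_TARGETS.copy(),
        min_heterospecific_reps=8,
    )


def _species_order(config: DesignConfig) -> list[str]:
    ordered = [s for s in SPECIES_ORDER if s in config.territory_counts]
    extra = [s for s in config.territory_counts if s not in SPECIES_ORDER]
    return ordered + sorted(extra)


def _male_ids(species: str, n: int) -> list[str]:
    # male ids are globally unique (the nesting of males in species is by label)
    slug = species.replace(" ", "-")
    return [f"{slug}-{i + 1:02d}" for i in range(n)]


def _check_feasibility(config: DesignConfig, species: list[str]) -> None:
    k = len(species)
    for i, sp in enumerate(species):
        n_males = config.territory_counts[sp]
        if n_males < 1:
            raise InfeasibleDesignError(f"species {sp!r} has no territories")
        hetero_cap = n_males * (config.max_stimuli_per_male - 1)
        needed = config.min_heterospecific_reps * (k - 1)
        if config.trial_targets is not None:
            row = config.trial_targets[i]
            hetero = int(row.sum() - row[i])
            if row[i] < n_males:
                raise InfeasibleDesignError(
                    f"trial targets give {int(row[i])} conspecific trials for {sp!r} "
                    f"but {n_males} males each need at least one"
                )
            off = np.delete(row, i)
            if config.min_heterospecific_reps and (off < config.min_heterospecific_reps).any():
                raise InfeasibleDesignError(
                    f"trial targets violate the minimum of "
                    f"{config.min_heterospecific_reps} heterospecific repetitions for {sp!r}"
                )
            total = int(row.sum())
            if total > n_males * config.max_stimuli_per_male:
                raise InfeasibleDesignError(
                    f"trial targets require {total} trials for {sp!r} but the cap of "
                    f"{config.max_stimuli_per_male} stimuli per male allows at most "
                    f"{n_males * config.max_stimuli_per_male}"
                )
        elif config.min_heterospecific_reps and needed > hetero_cap:
            raise InfeasibleDesignError(
                f"minimum heterospecific repetitions unreachable for {sp!r}: "
                f"need {needed} heterospecific trials but at most {hetero_cap} "
                f"fit under the {config.max_stimuli_per_male}-stimulus cap"
            )
        n_trials_min = 1 + config.n_heterospecific_per_male
        if config.trial_targets is None and n_trials_min > config.max_stimuli_per_male:
            raise InfeasibleDesignError(
                "1 conspecific + "
                f"{config.n_heterospecific_per_male} heterospecific stimuli exceed the "
                f"cap of {config.max_stimuli_per_male} stimuli per male"
            )


def _assign_from_targets(
    rng: np.random.Generator,
    species: list[str],
    config: DesignConfig,
    groups: dict[str, str],
) -> dict[str, list[str]]:
    """Per-male stimulus lists reproducing the target grid exactly."""
    idx = {s: i for i, s in enumerate(species)}
    targets = config.trial_targets
    stimuli: dict[str, list[str]] = {}
    for sp in species:
        n_males = config.territory_counts[sp]
        males = _male_ids(sp, n_males)
        i = idx[sp]
        consp: dict[str, list[str]] = {m: [sp] for m in males}
        # Extra conspecific trials beyond one per male (the printed grid has
        # more conspecific trials than territories for one species).
        extra_consp = int(targets[i, i]) - n_males
        for m in rng.choice(males, size=extra_consp, replace=False):
            consp[m].append(sp)
        hetero_slots: list[str] = []
        for sq in species:
            if sq != sp:
                hetero_slots += [sq] * int(targets[i, idx[sq]])
        # Randomized assignment of heterospecific slots under the per-male cap.
        # Filling males with the fewest heterospecific stimuli first keeps the
        # two-heterospecific minimum reachable; within a male we prefer
        # playback species it has not heard and, when configured, the
        # heterospecific treatment class (intra/extra) it has not yet
        # received, which balances treatments across males; restart on the
        # rare dead end.
        group = {s: groups[s] for s in species}
        for attempt in range(500):
            order = list(rng.permutation(hetero_slots))
            hetero: dict[str, list[str]] = {m: [] for m in males}
            cap = {m: config.max_stimuli_per_male - len(consp[m]) for m in males}
            ok = True
            for slot in order:
                cands = [m for m in males if len(hetero[m]) < cap[m]]
                if not cands:
                    ok = False
                    break

                def priority(m: str) -> tuple:
                    has_class = (
                        any(group[q] == group[slot] for q in hetero[m])
                        if config.balance_treatments_within_male
                        else False
                    )
                    return (len(hetero[m]), slot in hetero[m], has_class)

                best = min(priority(m) for m in cands)
                pool = [m for m in cands if priority(m) == best]
                hetero[pool[rng.integers(len(pool))]].append(slot)
            if ok and all(len(hetero[m]) >= 2 for m in males):
                stimuli.update({m: consp[m] + hetero[m] for m in males})
                break
        else:  # pragma: no cover - restarts exhaust only for adversarial grids
            raise InfeasibleDesignError(
                f"could not allocate heterospecific stimuli for {sp!r} under the "
                f"{config.max_stimuli_per_male}-stimulus cap"
            )
    return stimuli


def _assign_free(
    rng: np.random.Generator,
    species: list[str],
    config: DesignConfig,
    groups: dict[str, str],
) -> dict[str, list[str]]:
    """Per-male stimulus lists without a target grid: 1 conspecific plus
    randomly chosen heterospecifics, balanced toward the min-reps rule."""
    stimuli: dict[str, list[str]] = {}
    for sp in species:
        others = [s for s in species if s != sp]
        males = _male_ids(sp, config.territory_counts[sp])
        extra = set(
            rng.choice(males, size=min(config.n_males_with_extra, len(males)), replace=False)
        ) if config.n_males_with_extra else set()
        counts = {q: 0 for q in others}
        for m in males:
            k = config.n_heterospecific_per_male + (1 if m in extra else 0)
            k = min(k, config.max_stimuli_per_male - 1, len(others))
            # favour under-represented playback species so min reps are met,
            # and when balancing, species from under-represented treatment
            # classes within this male
            chosen: list[str] = []
            for _ in range(k):
                avail = [q for q in others if q not in chosen]
                if config.balance_treatments_within_male:
                    have = {groups[q] for q in chosen}
                    fresh = [q for q in avail if groups[q] not in have]
                    if fresh:
                        avail = fresh
                weights = np.array([1.0 / (1 + counts[q]) for q in avail])
                chosen.append(rng.choice(avail, p=weights / weights.sum()))
            for q in chosen:
                counts[q] += 1
            stimuli[m] = [sp] + chosen
        if config.min_heterospecific_reps:
            short = {q: c for q, c in counts.items() if c < config.min_heterospecific_reps}
            if short:
                raise InfeasibleDesignError(
                    f"minimum heterospecific repetitions not met for focal {sp!r}: {short}"
                )
    return stimuli


def _sample_days(rng: np.random.Generator, n: int, config: DesignConfig) -> np.ndarray:
    """Increasing trial days for one male with the configured minimum gap."""
    span = (n - 1) * config.min_gap_days
    slack = config.n_days - 1 - span
    if slack < 0:
        raise InfeasibleDesignError(
            f"{n} trials with a {config.min_gap_days}-day gap do not fit in "
            f"{config.n_days} days"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=n + 1))
    parts = np.diff(cuts)  # n nonnegative extras summing to <= slack
    gaps = np.full(n, config.min_gap_days)
    gaps[0] = 0
    days = 1 + parts[0] + np.cumsum(gaps + np.concatenate([[0], parts[1:]]))
    return days


def sample_schedule(config: DesignConfig | None = None, seed: int = 0,
                    species_table: list[SpeciesSpec] | None = None) -> pd.DataFrame:
    """Generate a randomized trial schedule satisfying the design rules.

    Returns a tidy frame with one row per trial (``SCHEDULE_COLUMNS``),
    reproducible under a fixed seed.
    """
    config = paper_design() if config is None else config
    table = default_species_table() if species_table is None else species_table
    species = _species_order(config)
    unknown = [s for s in species if s not in {sp.species_id for sp in table}]
    if unknown:
        raise KeyError(f"territory counts reference unknown species {unknown}")
    _check_feasibility(config, species)

    rng = np.random.default_rng(derive_seed(seed, "schedule"))
    groups = habitat_group_map(table)
    if config.trial_targets is not None:
        stimuli = _assign_from_targets(rng, species, config, groups)
    else:
        stimuli = _assign_free(rng, species, config, groups)

    male_species = {}
    for sp in species:
        for m in _male_ids(sp, config.territory_counts[sp]):
            male_species[m] = sp

    lo, hi = config.minutes_after_sunrise_range
    rows = []
    for m in sorted(stimuli):
        sp = male_species[m]
        order = list(rng.permutation(stimuli[m]))  # randomized stimulus order
        days = _sample_days(rng, len(order), config)
        for seq, (q, day) in enumerate(zip(order, days), start=1):
            rows.append(
                {
                    "trial_id": f"{m}-t{seq}",
                    "male_id": m,
                    "species": sp,
                    "playback_species": q,
                    "treatment": classify_treatment(sp, q, table),
                    "trial_seq": seq,
                    "day": int(day),
                    "minutes_after_sunrise": float(np.round(rng.uniform(lo, hi), 1)),
                    "already_singing": int(rng.random() < config.p_already_singing),
                }
            )
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)
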