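"""Design bookkeeping: recompute and validate a schedule's trial counts.

Reproduces the experiment's treatment-combination accounting (the 5x5 focal
x playback count grid with marginals, treatment totals and territory totals)
and checks every configurable design rule against a schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignConfig
from .species import SpeciesSpec, classify_treatment, default_species_table


@dataclass
class AuditCounts:
    cell_counts: pd.DataFrame        # focal x playback grid
    treatment_totals: dict[str, int]
    grand_total: int
    territory_counts: dict[str, int]  # males per focal species
    row_totals: dict[str, int]
    col_totals: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "cell_counts": {
                focal: {pb: int(v) for pb, v in row.items()}
                for focal, row in self.cell_counts.iterrows()
            },
            "treatment_totals": self.treatment_totals,
            "grand_total": self.grand_total,
            "territory_counts": self.territory_counts,
            "row_totals": self.row_totals,
            "col_totals": self.col_totals,
        }


def counts_from_grid(
    grid: pd.DataFrame, species_table: list[SpeciesSpec] | None = None
) -> AuditCounts:
    """Treatment accounting for an explicit focal x playback count grid."""
    table = default_species_table() if species_table is None else species_table
    totals = {"conspecific": 0, "intra_habitat": 0, "extra_habitat": 0}
    for focal in grid.index:
        for pb in grid.columns:
            t = classify_treatment(str(focal), str(pb), table)
            totals[t] += int(grid.loc[focal, pb])
    return AuditCounts(
        cell_counts=grid.astype(int),
        treatment_totals=totals,
        grand_total=int(grid.to_numpy().sum()),
        territory_counts={},
        row_totals={str(f): int(v) for f, v in grid.sum(axis=1).items()},
        col_totals={str(p): int(v) for p, v in grid.sum(axis=0).items()},
    )


def treatment_counts(
    schedule: pd.DataFrame, species_table: list[SpeciesSpec] | None = None
) -> AuditCounts:
    """Recompute the design bookkeeping from a trial schedule."""
    table = default_species_table() if species_table is None else species_table
    species = sorted(set(schedule["species"]) | set(schedule["playback_species"]))
    grid = (
        pd.crosstab(schedule["species"], schedule["playback_species"])
        .reindex(index=species, columns=species, fill_value=0)
    )
    counts = counts_from_grid(grid, table)
    counts.territory_counts = (
        schedule.groupby("species")["male_id"].nunique().astype(int).to_dict()
    )
    return counts


def check_constraints(
    schedule: pd.DataFrame,
    config: DesignConfig | None = None,
    adjacency: list[tuple[str, str]] | None = None,
) -> list[str]:
    """Check every configured design rule; returns human-readable violations.

    Rules: >= 1 conspecific and >= 2 heterospecific stimuli per male, at
    most ``max_stimuli_per_male`` stimuli per male, the experiment-wide
    minimum of heterospecific repetitions per focal x playback pair, no male
    tested twice on the same day, the minimum gap in days between a male's
    trials, and (only when an adjacency list is supplied) no two adjacent
    males tested on the same day.
    """
    config = DesignConfig() if config is None else config
    v: list[str] = []

    per_male = schedule.groupby("male_id")
    for male, grp in per_male:
        n_consp = int((grp["treatment"] == "conspecific").sum())
        n_het = len(grp) - n_consp
        if n_consp < 1:
            v.append(f"male {male}: no conspecific stimulus")
        if n_het < 2:
            v.append(f"male {male}: only {n_het} heterospecific stimuli (need >= 2)")
        if len(grp) > config.max_stimuli_per_male:
            v.append(
                f"male {male}: {len(grp)} stimuli exceed the cap of "
                f"{config.max_stimuli_per_male}"
            )
        days = grp["day"].to_numpy()
        dup_days = pd.Series(days).value_counts()
        for day, cnt in dup_days.items():
            if cnt > 1:
                v.append(f"male {male}: tested {cnt} times on day {int(day)}")
        if len(days) > 1:
            gaps = np.diff(np.sort(days))
            if (gaps < config.min_gap_days).any() and (gaps > 0).all():
                v.append(
                    f"male {male}: trials only {int(gaps.min())} day(s) apart "
                    f"(need >= {config.min_gap_days})"
                )

    if config.min_heterospecific_reps:
        het = schedule[schedule["species"] != schedule["playback_species"]]
        reps = het.groupby(["species", "playback_species"]).size()
        for sp in schedule["species"].unique():
            for pb in schedule["playback_species"].unique():
                if sp == pb:
                    continue
                n = int(reps.get((sp, pb), 0))
                if n < config.min_heterospecific_reps:
                    v.append(
                        f"focal {sp} x playback {pb}: {n} repetitions "
                        f"(need >= {config.min_heterospecific_reps})"
                    )

    # same-day neighbour rule is checked only when an adjacency list is given
    if adjacency is not None:
        pairs = {frozenset(p) for p in adjacency}
        by_day = schedule.groupby("day")["male_id"].apply(set)
        for day, males in by_day.items():
            for a in males:
                for b in males:
                    if a < b and frozenset((a, b)) in pairs:
                        v.append(
                            f"adjacent males {a} and {b} both tested on day {int(day)}"
                        )
    return v
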