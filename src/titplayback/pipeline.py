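"""End-to-end orchestration: simulate -> score -> audit -> fit ->
matrix-test -> territory, with one seed, per-stage sub-seeds, structured
logging and a run manifest.

Every stage reads only the CSV artifacts of earlier stages, so any stage
can be re-run in isolation from a directory of prior outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from ._rng import derive_seed
from .audit import check_constraints, treatment_counts
from .config import PipelineConfig
from .design import sample_schedule
from .ethogram import read_trials, summarize_trials
from .matrices import (
    aggression_matrix,
    mass_difference_matrix,
    permutation_matrix_test,
    song_similarity_matrix,
)
from .models import run_paper_models
from .scoring import build_index_table
from .simulate import (
    simulate_song_exemplars,
    simulate_territory_points,
    simulate_trials,
    truth_to_dict,
)
from .species import default_species_table
from .territory import map_territories, read_points

log = logging.getLogger("titplayback")


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log_stage(stage: str, **info) -> None:
    log.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in info.items()))


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    seed = derive_seed(config.seed, "simulate")
    table = default_species_table()
    schedule = sample_schedule(config.design, seed=seed)
    trials = simulate_trials(
        schedule, config.truth, seed=seed, renderer=config.renderer
    )
    songs = simulate_song_exemplars(
        table,
        n_exemplars=config.songs.n_exemplars,
        syllables_per_exemplar=config.songs.syllables_per_exemplar,
        seed=seed,
    )
    points = simulate_territory_points(
        schedule, seed=seed, n_points=config.territory.n_points
    )
    species_df = pd.DataFrame(
        [
            {"species": sp.species_id, "habitat_group": sp.habitat_group,
             "body_mass_g": sp.body_mass}
            for sp in table
        ]
    )
    _write(schedule, outdir / "schedule.csv")
    _write(trials, outdir / "trials.csv")
    _write(songs, outdir / "songs.csv")
    _write(points, outdir / "points.csv")
    _write(species_df, outdir / "species.csv")
    import yaml

    (outdir / "truth.yaml").write_text(yaml.safe_dump(truth_to_dict(config.truth)))
    _log_stage(
        "simulate", males=schedule["male_id"].nunique(), trials=len(schedule),
        trial_seconds=len(trials), songs=songs["exemplar_id"].nunique(),
    )
    return {"n_trials": len(schedule), "n_males": int(schedule["male_id"].nunique())}


def stage_score(config: PipelineConfig, outdir: Path) -> dict:
    series = read_trials(outdir / "trials.csv")
    variables = summarize_trials(
        series, max_visible_distance=config.renderer.max_visible_distance
    )
    index = build_index_table(variables, config.scaling)
    _write(variables, outdir / "variables.csv")
    _write(index, outdir / "index.csv")
    _log_stage("score", trials=len(variables), males=index["male_id"].nunique())
    return {"n_trials": len(index)}


def stage_audit(config: PipelineConfig, outdir: Path) -> dict:
    schedule = pd.read_csv(outdir / "schedule.csv")
    counts = treatment_counts(schedule)
    violations = check_constraints(schedule, config.design)
    report = {"counts": counts.to_dict(), "violations": violations}
    (outdir / "audit.json").write_text(json.dumps(report, indent=2))
    _log_stage(
        "audit", total=counts.grand_total, violations=len(violations),
        **counts.treatment_totals,
    )
    return report


def stage_fit(config: PipelineConfig, outdir: Path) -> dict:
    index = pd.read_csv(outdir / "index.csv")
    report = run_paper_models(
        index, species_vc=config.model.species_vc, df_method=config.model.df_method
    )
    (outdir / "fits.json").write_text(json.dumps(report, indent=2, default=float))
    contrasts = []
    contrasts += [dict(c, model="global") for c in report["global"]["contrasts"]]
    for sp, block in report["per_species"].items():
        contrasts += [dict(c, model=f"species:{sp}") for c in block["contrasts"]]
    for resp, block in report["per_variable"].items():
        contrasts += [dict(c, model=f"variable:{resp}") for c in block["contrasts"]]
    _write(pd.DataFrame(contrasts), outdir / "contrasts.csv")
    _log_stage("fit", n_obs=report["global"]["fit"]["n_obs"],
               models=1 + len(report["per_species"]) + len(report["per_variable"]))
    return report


def stage_matrix_test(config: PipelineConfig, outdir: Path) -> dict:
    index = pd.read_csv(outdir / "index.csv")
    songs = pd.read_csv(outdir / "songs.csv")
    table = default_species_table()
    labels = tuple(sp.species_id for sp in table)
    seed = derive_seed(config.seed, "matrix-test")

    aggr = aggression_matrix(index, labels=labels)
    mass = mass_difference_matrix(table, signed=config.permutation.signed_mass)
    song = song_similarity_matrix(songs, labels=labels)

    results = {}
    for name, predictor in (("mass", mass), ("song", song)):
        results[name] = permutation_matrix_test(
            aggr,
            predictor,
            n_perm=config.permutation.n_perm,
            seed=derive_seed(seed, name),
            use_diagonal=config.permutation.use_diagonal,
            method=config.permutation.method,
            symmetrize_response=config.permutation.symmetrize_response,
        )
    aggr.to_frame().to_csv(outdir / "aggression_matrix.csv")
    mass.to_frame().to_csv(outdir / "mass_matrix.csv")
    song.to_frame().to_csv(outdir / "song_matrix.csv")
    (outdir / "matrix_tests.json").write_text(json.dumps(results, indent=2))
    _log_stage(
        "matrix-test",
        r_mass=round(results["mass"]["r"], 3), p_mass=results["mass"]["p_value"],
        r_song=round(results["song"]["r"], 3), p_song=results["song"]["p_value"],
    )
    return results


def stage_territory(config: PipelineConfig, outdir: Path) -> dict:
    observations = read_points(outdir / "points.csv")
    vertices, areas = map_territories(
        observations, percentile=config.territory.percentile
    )
    _write(vertices, outdir / "territories.csv")
    _write(areas, outdir / "areas.csv")
    _log_stage(
        "territory", territories=len(areas),
        mean_area_m2=round(float(areas["area_m2"].mean()), 1),
    )
    return {"n_territories": len(areas),
            "mean_area_m2": float(areas["area_m2"].mean())}


STAGES = {
    "simulate": stage_simulate,
    "score": stage_score,
    "audit": stage_audit,
    "fit": stage_fit,
    "matrix-test": stage_matrix_test,
    "territory": stage_territory,
}

_INPUT_FILES = [
    "schedule.csv", "trials.csv", "songs.csv", "points.csv", "species.csv",
    "variables.csv", "index.csv",
]


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order and write a manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in ("simulate", "score", "audit", "fit", "matrix-test", "territory"):
        STAGES[stage](config, outdir)
    manifest = {
        "package": "titplayback",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "design": {
                k: (v.tolist() if hasattr(v, "tolist") else v)
                for k, v in dataclasses.asdict(config.design).items()
            },
            "truth": truth_to_dict(config.truth),
        },
        "files": {
            name: _sha256(outdir / name)
            for name in _INPUT_FILES
            if (outdir / name).exists()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
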