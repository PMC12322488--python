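"""YAML pipeline configuration with schema validation.

A config file has optional sections ``design``, ``truth``, ``renderer``,
``scaling``, ``model``, ``permutation``, ``songs`` and ``territory`` plus
top-level ``seed``; every key must match a field of the corresponding
dataclass, and schema violations report the offending key path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .design import DesignConfig
from .scoring import ScalingConfig
from .simulate import RendererConfig, TruthParams, truth_from_dict


class ConfigError(ValueError):
    """A configuration schema violation, naming the offending key path."""


@dataclass
class ModelConfig:
    species_vc: bool = True
    df_method: str = "residual"


@dataclass
class PermutationConfig:
    n_perm: int = 10_000
    method: str = "pearson"
    use_diagonal: bool = False
    symmetrize_response: bool = False
    signed_mass: bool = False


@dataclass
class SongConfig:
    n_exemplars: int = 3
    syllables_per_exemplar: int = 8


@dataclass
class TerritoryConfig:
    percentile: float = 100.0
    n_points: int = 20


@dataclass
class PipelineConfig:
    seed: int = 0
    design: DesignConfig = field(default_factory=DesignConfig)
    truth: TruthParams = field(default_factory=TruthParams)
    renderer: RendererConfig = field(default_factory=RendererConfig)
    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    songs: SongConfig = field(default_factory=SongConfig)
    territory: TerritoryConfig = field(default_factory=TerritoryConfig)


_SECTIONS = {
    "design": DesignConfig,
    "renderer": RendererConfig,
    "scaling": ScalingConfig,
    "model": ModelConfig,
    "permutation": PermutationConfig,
    "songs": SongConfig,
    "territory": TerritoryConfig,
}


def _build_section(cls, payload: dict, path: str):
    if not isinstance(payload, dict):
        raise ConfigError(f"section {path!r} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(payload) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under {path!r}")
    coerced = {}
    for key, value in payload.items():
        if key == "trial_targets" and value is not None:
            value = np.asarray(value, dtype=int)
        if key == "territory_counts" and value is not None:
            value = dict(value)
        if isinstance(value, list) and isinstance(known[key].default, tuple):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid section {path!r}: {err}") from err


def load_config(path, require: tuple[str, ...] = ()) -> PipelineConfig:
    """Load and validate a YAML pipeline config.

    ``require`` names sections that must be present (e.g. a full pipeline
    run requires an explicit ``truth``); everything else falls back to the
    documented defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    for name in require:
        if name not in raw:
            raise ConfigError(f"config missing required section {name!r}")
    allowed = set(_SECTIONS) | {"truth", "seed"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")

    kwargs: dict = {}
    if "seed" in raw:
        if not isinstance(raw["seed"], int):
            raise ConfigError("'seed' must be an integer")
        kwargs["seed"] = raw["seed"]
    if "truth" in raw:
        try:
            kwargs["truth"] = truth_from_dict(raw["truth"])
        except (KeyError, TypeError, ValueError) as err:
            raise ConfigError(f"invalid section 'truth': {err}") from err
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name], name)
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig, path) -> None:
    """Write a PipelineConfig back to YAML (inverse of load_config)."""
    from .simulate import truth_to_dict

    doc: dict = {"seed": config.seed, "truth": truth_to_dict(config.truth)}
    for name in _SECTIONS:
        section = dataclasses.asdict(getattr(config, name))
        if name == "design" and section.get("trial_targets") is not None:
            section["trial_targets"] = np.asarray(section["trial_targets"]).tolist()
        doc[name] = section
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
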