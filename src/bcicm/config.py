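"""YAML experiment configuration: a flat key schema mirroring the CLI flags.

Recognized keys (all optional; defaults in parentheses):

    resolution (40)          n_levels (8)          distance (1)
    angles ([0,45,90,135])   symmetric (true)      average_angles (true)
    include_optional (false) pop_size (30)         max_iter (200)
    seed (0)                 split_fraction (0.8)  split_seed (0)
    feature_scaling (minmax)

Unknown keys are rejected by name, with a closest-match suggestion.
"""

from __future__ import annotations

import difflib
from dataclasses import asdict
from pathlib import Path

import yaml

from .errors import ConfigError
from .pipeline import ExperimentConfig
from .texture import GLCMParams
from .udlm import UDLMConfig

_KNOWN_KEYS = (
    "resolution",
    "n_levels",
    "distance",
    "angles",
    "symmetric",
    "average_angles",
    "include_optional",
    "pop_size",
    "max_iter",
    "seed",
    "split_fraction",
    "split_seed",
    "feature_scaling",
)


def config_from_mapping(mapping: dict | None) -> ExperimentConfig:
    mapping = dict(mapping or {})
    for key in mapping:
        if key not in _KNOWN_KEYS:
            suggestion = difflib.get_close_matches(str(key), _KNOWN_KEYS, n=1)
            hint = f"; did you mean {suggestion[0]!r}?" if suggestion else ""
            raise ConfigError(f"unknown configuration key {key!r}{hint}")
    glcm = GLCMParams(
        distance=int(mapping.get("distance", 1)),
        angles=tuple(mapping.get("angles", (0, 45, 90, 135))),
        n_levels=int(mapping.get("n_levels", 8)),
        symmetric=bool(mapping.get("symmetric", True)),
        average_angles=bool(mapping.get("average_angles", True)),
    )
    udlm = UDLMConfig(
        pop_size=int(mapping.get("pop_size", 30)),
        max_iter=int(mapping.get("max_iter", 200)),
        seed=int(mapping.get("seed", 0)),
    )
    return ExperimentConfig(
        resolution=int(mapping.get("resolution", 40)),
        glcm=glcm,
        udlm=udlm,
        include_optional=bool(mapping.get("include_optional", False)),
        split_fraction=float(mapping.get("split_fraction", 0.8)),
        split_seed=int(mapping.get("split_seed", 0)),
        feature_scaling=str(mapping.get("feature_scaling", "minmax")),
    )


def parse_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML config file; an empty file yields all defaults."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping of keys to values")
    return config_from_mapping(data)


def config_to_mapping(config: ExperimentConfig) -> dict:
    """Flat-key snapshot of a config (the inverse of ``config_from_mapping``)."""
    return {
        "resolution": config.resolution,
        "n_levels": config.glcm.n_levels,
        "distance": config.glcm.distance,
        "angles": list(config.glcm.angles),
        "symmetric": config.glcm.symmetric,
        "average_angles": config.glcm.average_angles,
        "include_optional": config.include_optional,
        "pop_size": config.udlm.pop_size,
        "max_iter": config.udlm.max_iter,
        "seed": config.udlm.seed if config.udlm.seed is not None else 0,
        "split_fraction": config.split_fraction,
        "split_seed": config.split_seed,
        "feature_scaling": config.feature_scaling,
    }


def emit_defaults() -> str:
    """Serialize the default configuration as YAML."""
    return yaml.safe_dump(config_to_mapping(ExperimentConfig()), sort_keys=False)
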