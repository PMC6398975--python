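"""Configuration files, seed management, tidy CSV/JSON writers, run manifests.

Config files are flat YAML/JSON documents whose keys are the transliterated
model symbols (p_c, p_n, n_guides, p_nf, p_y, xo_fertility, p_x_xo, f_max,
litter_mean, r_max, ...).  Unknown keys are rejected.
"""
from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import ReplicateSummary, SimResult
from .params import (
    DemogParams,
    DriveParams,
    Placement,
    SimConfig,
    Strategy,
    XShredderParams,
)

__all__ = [
    "ConfigError",
    "UnknownConfigKey",
    "ConfigValueError",
    "CONFIG_KEYS",
    "load_config",
    "build_config",
    "config_to_dict",
    "write_trajectories",
    "read_trajectories",
    "write_summary",
    "spawn_seeds",
    "RunManifest",
    "replay",
]


class ConfigError(ValueError):
    """Base class for configuration problems."""


class UnknownConfigKey(ConfigError):
    pass


class ConfigValueError(ConfigError):
    pass


# key -> (dataclass section, field name, coercion)
CONFIG_KEYS: dict[str, tuple[str, str, type]] = {
    "p_c": ("drive", "cut_prob", float),
    "p_n": ("drive", "nhej_prob", float),
    "n_guides": ("drive", "n_guides", int),
    "p_nf": ("drive", "nonfunctional_prob", float),
    "p_y": ("drive", "shred_prob", float),
    "xo_fertility": ("drive", "xo_fertility", float),
    "p_x_xo": ("drive", "x_bias_xo", float),
    "placement": ("drive", "placement", str),
    "k": ("demog", "carrying_capacity", int),
    "litter_mean": ("demog", "litter_mean", float),
    "r_max": ("demog", "r_max", float),
    "f_max": ("demog", "max_mates", int),
    "cycles_per_year": ("demog", "cycles_per_year", int),
    "p_x": ("xshredder", "shred_prob_x", float),
    "p_y_yo": ("xshredder", "y_transmission_yo", float),
    "per_gamete_shredding": ("xshredder", "per_gamete", bool),
    "strategy": ("top", "strategy", str),
    "inoculum_size": ("top", "inoculum_size", int),
    "years": ("top", "years", int),
    "replicates": ("top", "replicates", int),
    "seed": ("top", "seed", int),
}

_SECTIONS = {"drive": DriveParams, "demog": DemogParams, "xshredder": XShredderParams}


def build_config(values: dict) -> SimConfig:
    """Build a validated SimConfig from a flat key-value mapping, with the
    baseline parameterization as the default for absent keys."""
    unknown = set(values) - set(CONFIG_KEYS)
    if unknown:
        raise UnknownConfigKey(f"unknown configuration key(s): {sorted(unknown)}")
    per_section: dict[str, dict] = {"drive": {}, "demog": {}, "xshredder": {}, "top": {}}
    for key, raw in values.items():
        section, fname, coerce = CONFIG_KEYS[key]
        try:
            per_section[section][fname] = coerce(raw)
        except (TypeError, ValueError) as exc:
            raise ConfigValueError(f"bad value for {key!r}: {raw!r} ({exc})") from exc
    try:
        return SimConfig(
            drive=DriveParams(**per_section["drive"]),
            demog=DemogParams(**per_section["demog"]),
            xshredder=XShredderParams(**per_section["xshredder"]),
            **per_section["top"],
        )
    except ValueError as exc:
        raise ConfigValueError(str(exc)) from exc


def load_config(path: str | Path) -> SimConfig:
    """Parse a YAML/JSON config file into a validated SimConfig."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a flat mapping")
    return build_config(data)


def config_to_dict(config: SimConfig) -> dict:
    """Flat parameter echo of a SimConfig, using the file/CLI key names."""
    out = {}
    for key, (section, fname, _) in CONFIG_KEYS.items():
        obj = config if section == "top" else getattr(config, section)
        val = getattr(config, fname) if section == "top" else getattr(obj, fname)
        if isinstance(val, (Placement, Strategy)):
            val = val.value
        out[key] = val
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_trajectories(results: Sequence[SimResult] | SimResult, path: str | Path) -> Path:
    """Tidy per-cycle CSV: replicate, year, cycle, N, XX, XY, XO, WW, WG, GG,
    WR, GR, RR, eradicated."""
    if isinstance(results, SimResult):
        results = [results]
    frames = [r.to_frame(replicate=i) for i, r in enumerate(results)]
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_trajectories(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_summary(summary: ReplicateSummary, path: str | Path) -> Path:
    payload = {
        "eradication_probability": summary.eradication_probability,
        "n_replicates": summary.n_replicates,
        "final_n_mean": summary.final_n_mean,
        "final_n_lo": summary.final_n_lo,
        "final_n_hi": summary.final_n_hi,
        "eradication_cycles": summary.eradication_cycles,
        "cycles_per_year": summary.cycles_per_year,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path


# ---------------------------------------------------------------------------
# Seeds and manifests
# ---------------------------------------------------------------------------


def spawn_seeds(root_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Deterministic, collision-free child seed streams (SeedSequence.spawn)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.SeedSequence(root_seed).spawn(n)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bitwise: the full flat parameter
    echo (including the root seed) plus provenance metadata."""

    config: dict
    root_seed: int
    replicates: int
    version: str = __version__
    created: str = ""
    command: str | None = None

    def __post_init__(self) -> None:
        if not self.created:
            self.created = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    @classmethod
    def for_run(cls, config: SimConfig, command: str | None = None) -> "RunManifest":
        return cls(
            config=config_to_dict(config),
            root_seed=config.seed,
            replicates=config.replicates,
            command=command,
        )


def replay(manifest: RunManifest) -> list[SimResult]:
    """Re-run the batch described by a manifest; output is bitwise identical."""
    from .engine import run_replicate_batch

    config = build_config(manifest.config)
    return run_replicate_batch(config, manifest.replicates)
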