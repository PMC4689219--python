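"""Run configuration: loading, validation, defaults and serialisation.

A run is described by a flat YAML file with ``model:``, ``protocol:``,
``population:``, ``noise:`` and ``analysis:`` sections.  Unknown keys are
rejected and every validation error names the offending key.  The shipped
``defaults.yaml`` provides all values; a user file overrides any subset.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Dict

import yaml

from .params import (DoseDistribution, ModelParameters, NoiseModel,
                     ParameterError, PulseProtocol)

__all__ = ["RunConfig", "AnalysisSettings", "load_config", "save_config",
           "default_config", "ConfigError", "config_hash"]


class ConfigError(ValueError):
    """Raised on malformed configuration files."""


@dataclass(frozen=True)
class AnalysisSettings:
    """Settings for the analysis stages (ROC, clustering, peaks, sweep)."""

    n_boot: int = 1000
    frame_interval: float = 0.25
    cluster_k: int = 2
    kde_bandwidth: Any = "silverman"
    peak_prominence_frac: float = 0.05
    s_levels: tuple = (1.0, 0.5, 0.25)

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ParameterError("n_boot: must be >= 1")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval: must be positive")
        if self.cluster_k < 1:
            raise ParameterError("cluster_k: must be >= 1")
        if not 0 < self.peak_prominence_frac < 1:
            raise ParameterError("peak_prominence_frac: must be in (0,1)")
        object.__setattr__(self, "s_levels",
                           tuple(float(s) for s in self.s_levels))

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["s_levels"] = list(d["s_levels"])
        return d


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved pipeline configuration."""

    model: ModelParameters
    protocol: PulseProtocol
    dose: DoseDistribution
    n: int
    seed: int
    noise: NoiseModel
    analysis: AnalysisSettings
    version: str = "0.1.0"

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "protocol": self.protocol.to_dict(),
            "population": {"dose_family": self.dose.family,
                           "dose_location": self.dose.location,
                           "dose_scale": self.dose.scale,
                           "n": self.n, "seed": self.seed},
            "noise": self.noise.to_dict(),
            "analysis": self.analysis.to_dict(),
            "version": self.version,
        }


def _default_dict() -> Dict[str, Any]:
    text = (importlib.resources.files("fateswitch") / "defaults.yaml") \
        .read_text()
    return yaml.safe_load(text)


def _merge_section(defaults: Dict[str, Any], user: Dict[str, Any],
                   section: str) -> Dict[str, Any]:
    base = dict(defaults.get(section, {}))
    extra = user.get(section)
    if extra is None:
        return base
    if not isinstance(extra, dict):
        raise ConfigError(f"{section}: expected a mapping")
    for key, val in extra.items():
        if key not in base:
            raise ConfigError(f"{section}.{key}: unknown key")
        base[key] = val
    return base


def _build(raw: Dict[str, Any]) -> RunConfig:
    defaults = _default_dict()
    known_sections = set(defaults) | {"version"}
    for key in raw:
        if key not in known_sections:
            raise ConfigError(f"{key}: unknown section")
    model_d = _merge_section(defaults, raw, "model")
    proto_d = _merge_section(defaults, raw, "protocol")
    pop_d = _merge_section(defaults, raw, "population")
    noise_d = _merge_section(defaults, raw, "noise")
    ana_d = _merge_section(defaults, raw, "analysis")
    version = raw.get("version", defaults.get("version", "0.1.0"))
    try:
        model = ModelParameters(**model_d)
        protocol = PulseProtocol(**proto_d)
        dose = DoseDistribution(family=pop_d["dose_family"],
                                location=float(pop_d["dose_location"]),
                                scale=float(pop_d["dose_scale"]))
        noise = NoiseModel(**noise_d)
        analysis = AnalysisSettings(**ana_d)
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    n = int(pop_d["n"])
    if n < 1:
        raise ConfigError("population.n: must be >= 1")
    return RunConfig(model=model, protocol=protocol, dose=dose, n=n,
                     seed=int(pop_d["seed"]), noise=noise,
                     analysis=analysis, version=str(version))


def default_config() -> RunConfig:
    """The shipped defaults as a resolved :class:`RunConfig`."""
    return _build({})


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys fall back to the shipped defaults; an empty file (or
    ``None``) yields the full default configuration.  Unknown or
    out-of-range keys raise :class:`ConfigError` naming the key.
    """
    if path is None:
        return default_config()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of config must be a mapping")
    return _build(raw)


def save_config(config: RunConfig, path: str | Path) -> Path:
    """Serialise a resolved configuration back to YAML (round-trips with
    :func:`load_config`)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the resolved configuration, for provenance."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
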