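"""Run configuration: a YAML-backed dataclass tree with strict keys.

Unknown keys are rejected so typos fail loudly; a config round-trips through
:func:`save_config`/:func:`load_config` losslessly. The seed is mandatory —
every stochastic stage of a run derives from it.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class PathsConfig:
    stacks_dir: str = ""
    layout_csv: str = ""
    output_dir: str = "results"


@dataclass
class AnalysisConfig:
    responsive_threshold: float = 0.1
    hit_cutoff: float = 0.9
    zprime_variant: str = "canonical"
    autofluor_k_sd: float = 5.0
    toxic_fraction: float = 0.3
    min_responsive_cells: int = 20

    def __post_init__(self) -> None:
        for name in ("responsive_threshold", "hit_cutoff", "autofluor_k_sd",
                     "toxic_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"analysis.{name} must be positive")
        if self.zprime_variant not in ("canonical", "as_printed"):
            raise ValueError(f"unknown zprime variant {self.zprime_variant!r}")


@dataclass
class SimulationConfig:
    enabled: bool = False
    n_compounds: int = 8
    n_replicates: int = 4
    n_cells: int = 175
    field_height: int = 512
    field_width: int = 512
    genotype_amplitude: float = 3.0
    responder_fraction: float = 0.96
    photon_noise_scale: float = 1.0
    n_dmso: int = 16
    n_tp: int = 16
    compound_suppression: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    seed: int = None  # type: ignore[assignment]
    paths: PathsConfig = field(default_factory=PathsConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config requires a seed")
        self.seed = int(self.seed)


def _build(cls, data: dict, crumb: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) under {crumb}: {sorted(unknown)}")
    return cls(**data)


def from_dict(data: dict) -> RunConfig:
    sections = {
        "paths": PathsConfig,
        "analysis": AnalysisConfig,
        "simulation": SimulationConfig,
    }
    unknown = set(data) - set(sections) - {"seed"}
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {"seed": data.get("seed")}
    for name, cls in sections.items():
        kwargs[name] = _build(cls, data.get(name) or {}, name)
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return from_dict(data)


def to_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(to_dict(config), sort_keys=True))
    return path


def config_hash(config: RunConfig) -> str:
    """Stable hash of the full configuration, stamped into every output."""
    canonical = yaml.safe_dump(to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
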