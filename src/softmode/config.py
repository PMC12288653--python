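"""Strict YAML run configuration.

Every stochastic component draws from a substream derived from the single
global seed plus a named salt (see :func:`softmode.io.substream`), so runs
are reproducible and adding new components never shifts existing streams.
Unknown keys are rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from softmode.evolution import AnnealConfig, FitnessConfig
from softmode.experiments import MutationSpec

__all__ = ["NetworkConfig", "ControllerConfig", "EnsembleConfig", "RunConfig", "load_config", "save_config"]


@dataclass
class NetworkConfig:
    n_genes: int = 10
    sparsity: float = 0.5
    decay: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("network.n_genes must be >= 1")
        if not 0 < self.sparsity <= 1:
            raise ValueError("network.sparsity must be in (0, 1]")


@dataclass
class ControllerConfig:
    k: int = 1
    c_p: float = 1.0
    c_i: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("controller.k must be >= 1")


@dataclass
class EnsembleConfig:
    env_sd: float = 0.1
    n_draws: int = 200

    def __post_init__(self) -> None:
        if self.env_sd <= 0:
            raise ValueError("ensemble.env_sd must be positive")
        if self.n_draws < 1:
            raise ValueError("ensemble.n_draws must be >= 1")


@dataclass
class RunConfig:
    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    anneal: AnnealConfig = field(default_factory=AnnealConfig)
    mutation: MutationSpec = field(default_factory=MutationSpec)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "network": NetworkConfig,
    "controller": ControllerConfig,
    "fitness": FitnessConfig,
    "anneal": AnnealConfig,
    "mutation": MutationSpec,
    "ensemble": EnsembleConfig,
}


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in [{section}]: {sorted(unknown)}")
    # YAML gives lists; dataclass defaults use tuples for bounds
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config; missing sections take defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {"seed": int(raw.get("seed", 0))}
    for name, cls in _SECTIONS.items():
        data = raw.get(name, {})
        if not isinstance(data, dict):
            raise ValueError(f"config section [{name}] must be a mapping")
        kwargs[name] = _build_section(cls, data, name)
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
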