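"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .simulate import SimulationConfig


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    mode: str = "simulate"  # simulate | fixture
    seed: int = 0

    # thresholds (defaults are the published constants)
    min_len: int = 70
    max_n_fraction: float = 0.05
    e_threshold: float = 1e-4
    min_frequency: float = 0.5
    motif_include_threshold: float = 0.25
    motif_dominance_threshold: float = 0.5
    n_permutations: int = 2000

    # stage toggles
    run_panel: bool = True
    run_consensus: bool = True
    run_peptides: bool = True
    run_expression: bool = True
    run_congruence: bool = True

    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if self.mode not in ("simulate", "fixture"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.min_len < 0 or not (0 <= self.max_n_fraction <= 1):
            raise ConfigError("invalid read-filter thresholds")
        if self.e_threshold <= 0:
            raise ConfigError("e_threshold must be positive")
        if not (0 <= self.min_frequency < 1):
            raise ConfigError("min_frequency must be in [0, 1)")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        # one seed drives every stage
        self.simulation.seed = self.seed

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["simulation"]["loop_length_range"] = list(
            self.simulation.loop_length_range
        )
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sim = data.pop("simulation", {})
        if "loop_length_range" in sim:
            sim["loop_length_range"] = tuple(sim["loop_length_range"])
        cfg = cls(**data)
        if sim:
            sim["seed"] = cfg.seed
            cfg.simulation = SimulationConfig(**sim)
        return cfg
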