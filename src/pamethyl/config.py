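"""Pipeline configuration: one YAML file drives a reproducible run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .simulate import SimulationConfig

__all__ = ["PipelineConfig", "StageToggles"]


@dataclass
class StageToggles:
    simulate: bool = True
    qc: bool = True
    bcsvd: bool = True
    filter_probes: bool = True
    validate: bool = True
    associate: bool = True
    enrich: bool = True


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    seed: int = 0
    out_dir: str = "run"
    stages: StageToggles = field(default_factory=StageToggles)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # QC
    detection_p_threshold: float = 0.01
    min_sample_fraction: float = 1.0
    n_components: int = 5
    outlier_z: float = 3.0
    # BCSVD
    prior_variance: float = 100.0
    n_iter: int = 2000
    burn_in: int = 500
    perm_n_iter: int = 600
    perm_burn_in: int = 100
    n_permutations: int = 99
    alpha: float = 0.05
    pooled_permutations: bool = False
    # validity
    max_mismatches: int = 7
    # association
    association_phenotype: str = "testosterone"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in d:
            stage_known = {f.name for f in fields(StageToggles)}
            bad = set(d["stages"]) - stage_known
            if bad:
                raise ValueError(f"unknown stage toggles: {sorted(bad)}")
            d["stages"] = StageToggles(**d["stages"])
        if "simulation" in d:
            sim_known = {f.name for f in fields(SimulationConfig)}
            bad = set(d["simulation"]) - sim_known
            if bad:
                raise ValueError(f"unknown simulation keys: {sorted(bad)}")
            d["simulation"] = SimulationConfig(**d["simulation"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
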