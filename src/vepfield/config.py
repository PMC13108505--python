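"""Run configuration: one YAML-serializable record of every knob.

The configuration is echoed verbatim into every result bundle so any run
can be reproduced from its outputs alone; unknown keys are rejected rather
than silently ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # geometry / transforms
    mesh_level: int = 4
    n_regions_per_hemi: int = 81
    grid_degree: int = 32  # simulation/operator truncation
    L_max: int = 16  # inference truncation of spatial maps
    radius_mm: float = 100.0
    # integration
    dt: float = 0.05
    n_steps: int = 600
    subsample_s: float = 0.1
    # scenario ground truth
    G: float = 1.0
    tau: float = 30.0
    n_ez: int = 3
    n_electrodes: int = 10
    contacts_per_electrode: int = 8
    n_augment: int = 50
    augment_sd: float = 0.1
    # optimizer
    learning_rate: float = 0.001
    opt_steps: int = 5000
    n_restarts: int = 4
    # classification / evaluation
    t_eps_s: float = 10.0
    pct_threshold: float = 20.0
    implant_radius_mm: float = 3.0
    # master seed; every stochastic step derives its own stream from it
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
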