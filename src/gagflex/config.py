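"""Pipeline configuration: a flat, YAML-round-trippable record of every
knob the pipeline exposes, validated up front so a bad value fails before
any computation."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .clustering import DEFAULT_RMSD_CUTOFF
from .features import (CONTACT_CUTOFF, HBOND_ANGLE_CUTOFF, HBOND_DIST_CUTOFF,
                       ION_PROXIMITY_CUTOFF)
from .fes import DEFAULT_TEMPERATURE
from .topology import GAG_KINDS


@dataclass
class PipelineConfig:
    # system
    gag_kind: str = "HA"
    n_disaccharides: int = 5
    # synthetic ensemble (ignored when a trajectory is supplied)
    n_frames: int = 1000
    seed: int = 0
    state_weights: tuple = (0.7, 0.3)
    concentration: float = 40.0
    kink_shift: float = -130.0
    n_ions: int = 0
    box_edge: float = 6.8
    # input trajectory (overrides the generator when set)
    topology_path: str | None = None
    trajectory_path: str | None = None
    # cutoffs (nm / degrees)
    contact_cutoff: float = CONTACT_CUTOFF
    hbond_dist_cutoff: float = HBOND_DIST_CUTOFF
    hbond_angle_cutoff: float = HBOND_ANGLE_CUTOFF
    ion_proximity_cutoff: float = ION_PROXIMITY_CUTOFF
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF
    # clustering
    cluster_max_frames: int = 400  # frames used for the pairwise matrix (strided)
    evolution_checkpoints: int = 10
    # FES / k-means
    temperature: float = DEFAULT_TEMPERATURE
    fes_bins: int = 50
    standardize: bool = True
    k_min: int = 1
    k_max: int = 8
    fixed_k: int | None = None
    # output
    output_dir: str = "gagflex_out"

    def validate(self) -> "PipelineConfig":
        if self.gag_kind not in GAG_KINDS:
            raise ValueError(f"gag_kind must be one of {GAG_KINDS}")
        for name in ("contact_cutoff", "hbond_dist_cutoff", "hbond_angle_cutoff",
                     "ion_proximity_cutoff", "rmsd_cutoff", "box_edge",
                     "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_frames < 1 or self.n_disaccharides < 1:
            raise ValueError("n_frames and n_disaccharides must be >= 1")
        if self.n_ions < 0:
            raise ValueError("n_ions must be >= 0")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        for p in (self.topology_path, self.trajectory_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return self

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["state_weights"] = list(self.state_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "state_weights" in d:
            d["state_weights"] = tuple(d["state_weights"])
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
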