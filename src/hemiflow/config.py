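"""Validated pipeline configuration loaded from YAML."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


def _from_dict(cls, data: dict, where: str):
    if not isinstance(data, dict):
        raise ValueError(f"{where}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _from_dict(f.type, v, f"{where}.{f.name}")
        kwargs[f.name] = v
    return cls(**kwargs)


def _check(cond, msg):
    if not cond:
        raise ValueError(f"config: {msg}")


@dataclass
class ParadigmConfig:
    n_blocks_per_condition: int = 4
    block_duration_s: float = 30.0
    tr_s: float = 3.0
    n_dummy: int = 5

    def __post_init__(self):
        _check(self.n_blocks_per_condition >= 1, "need at least one block")
        _check(self.tr_s > 0, "TR must be positive")


@dataclass
class GroupConfig:
    label: str = "LH"
    n_subjects: int = 6
    asymmetry_ratio: float = 1.0
    edge_deltas: list = field(default_factory=list)
    between_subject_sd: float = 0.05

    def __post_init__(self):
        _check(self.n_subjects >= 2, f"group {self.label}: n_subjects must be >= 2")
        _check(self.asymmetry_ratio > 0, "asymmetry_ratio must be positive")


@dataclass
class SimulationConfig:
    coupling: float = 0.35
    self_coupling: float = 0.3
    neural_noise_sd: float = 1.0
    bold_noise_sd: float = 0.5
    voxel_noise_sd: float = 1.0
    effect_scale: float = 1.0
    p_active: float = 0.5
    # task drive per region; occipital entry regions are driven hardest,
    # the rest receive the input mostly through the network
    input_gains: dict = field(
        default_factory=lambda: {
            "default": 1.0, "IOG_L": 2.0, "MOG_L": 2.0, "MOG_R": 2.0,
        }
    )
    groups: list = field(
        default_factory=lambda: [
            {"label": "LH", "asymmetry_ratio": 1.0,
             "edge_deltas": [["MOG_R", "INS_L", 0.35], ["MOG_R", "INS_R", 0.35]]},
            {"label": "RH", "asymmetry_ratio": 3.0},
        ]
    )

    def __post_init__(self):
        self.groups = [
            g if isinstance(g, GroupConfig)
            else _from_dict(GroupConfig, g, "simulation.groups")
            for g in self.groups
        ]
        _check(0 < self.p_active <= 1, "p_active must lie in (0, 1]")


@dataclass
class ActivationConfig:
    q: float = 0.01
    min_cluster: int = 10
    connectivity: int = 26
    drift_order: int = 1

    def __post_init__(self):
        _check(0 < self.q < 1, "FDR q must lie in (0, 1)")
        _check(self.connectivity in (6, 18, 26), "connectivity must be 6/18/26")


@dataclass
class LateralityConfig:
    n_steps: int = 40
    territories: dict = field(default_factory=lambda: {"cerebral": None})

    def __post_init__(self):
        _check(self.n_steps >= 4, "threshold grid needs at least 4 steps")


@dataclass
class ConnectivityConfig:
    basis: str = "canonical+derivatives"
    max_order: int = 5
    criterion: str = "aic"
    regularization: float = None
    n_reps: int = 100
    alpha: float = 0.05
    deconvolve: bool = True

    def __post_init__(self):
        _check(self.max_order >= 1, "max_order must be >= 1")
        _check(self.n_reps >= 100, "bootstrap n_reps must be >= 100")
        _check(0 < self.alpha < 0.5, "bootstrap alpha must lie in (0, 0.5)")


@dataclass
class ComparisonConfig:
    alpha_fwe: float = 0.01
    direction: str = "greater"
    count_alpha: float = 0.01
    alpha_group: float = 0.01

    def __post_init__(self):
        _check(0 < self.alpha_fwe < 1, "alpha_fwe must lie in (0, 1)")
        _check(self.direction in ("greater", "less"), "direction: greater/less")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "hemiflow_out"
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    activation: ActivationConfig = field(default_factory=ActivationConfig)
    laterality: LateralityConfig = field(default_factory=LateralityConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    comparison: ComparisonConfig = field(default_factory=ComparisonConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        for name, sub in (
            ("paradigm", ParadigmConfig),
            ("simulation", SimulationConfig),
            ("activation", ActivationConfig),
            ("laterality", LateralityConfig),
            ("connectivity", ConnectivityConfig),
            ("comparison", ComparisonConfig),
        ):
            if name in data:
                data[name] = _from_dict(sub, data[name], name)
        return _from_dict(cls, data, "config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self, include_paths: bool = False) -> dict:
        """Serialize; output paths are excluded by default so that the
        echoed config and its hash describe only the analysis itself."""
        d = dataclasses.asdict(self)
        if not include_paths:
            d.pop("out_dir", None)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
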