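"""Experiment configuration: plate layout, sub-configs, serialization.

An :class:`ExperimentConfig` bundles everything needed to run a seeded
virtual experiment: the condition arms (exactly one medium-control arm),
positions per condition, timepoints, the optical/reconstruction/
background/dry-mass parameter blocks, and the master seed.  Configs load
from YAML or JSON; file values override defaults, CLI flags override the
file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .background import BackgroundParams
from .drymass import DryMassParams
from .errors import ConfigError
from .holosim import OpticalConfig
from .phantom import ScenarioSpec
from .recon import ReconstructionParams

__all__ = ["ConditionSpec", "ExperimentConfig", "default_timepoints"]


def default_timepoints() -> list[float]:
    """Every 30 min for 24 h -> 49 samples."""
    return [0.5 * i for i in range(49)]


@dataclass(frozen=True)
class ConditionSpec:
    """One condition arm of the plate layout."""

    name: str
    scenario: ScenarioSpec
    concentration_ug_per_ml: float = 0.0
    is_control: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "scenario": self.scenario.to_dict(),
            "concentration_ug_per_ml": self.concentration_ug_per_ml,
            "is_control": self.is_control,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ConditionSpec":
        return cls(
            name=d["name"],
            scenario=ScenarioSpec.from_dict(d["scenario"]),
            concentration_ug_per_ml=d.get("concentration_ug_per_ml", 0.0),
            is_control=d.get("is_control", False),
        )


@dataclass
class ExperimentConfig:
    conditions: list[ConditionSpec]
    n_experiments: int = 3
    fovs_per_condition: int = 4  #: positions per well
    timepoints_h: list[float] = field(default_factory=default_timepoints)
    optical: OpticalConfig = field(default_factory=OpticalConfig)
    recon: ReconstructionParams = field(default_factory=ReconstructionParams)
    background: BackgroundParams = field(default_factory=BackgroundParams)
    drymass: DryMassParams = field(default_factory=DryMassParams)
    scene_kwargs: dict[str, Any] = field(default_factory=dict)
    master_seed: int = 0
    save_holograms: bool = False
    save_phase_maps: bool = True
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigError("at least one condition is required")
        n_control = sum(c.is_control for c in self.conditions)
        if n_control != 1:
            raise ConfigError(
                f"exactly one medium-control arm is required, found {n_control}"
            )
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ConfigError("condition names must be unique")
        if self.n_experiments < 1 or self.fovs_per_condition < 1:
            raise ConfigError("n_experiments and fovs_per_condition must be >= 1")
        if len(self.timepoints_h) < 2:
            raise ConfigError("at least two timepoints are required")
        if sorted(self.timepoints_h) != list(self.timepoints_h):
            raise ConfigError("timepoints must be increasing")

    @property
    def control(self) -> ConditionSpec:
        return next(c for c in self.conditions if c.is_control)

    def to_dict(self) -> dict[str, Any]:
        return {
            "conditions": [c.to_dict() for c in self.conditions],
            "n_experiments": self.n_experiments,
            "fovs_per_condition": self.fovs_per_condition,
            "timepoints_h": list(self.timepoints_h),
            "optical": self.optical.to_dict(),
            "recon": self.recon.to_dict(),
            "background": self.background.to_dict(),
            "drymass": self.drymass.to_dict(),
            "scene_kwargs": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in self.scene_kwargs.items()
            },
            "master_seed": self.master_seed,
            "save_holograms": self.save_holograms,
            "save_phase_maps": self.save_phase_maps,
            "make_plots": self.make_plots,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        try:
            return cls(
                conditions=[ConditionSpec.from_dict(c) for c in d["conditions"]],
                n_experiments=d.get("n_experiments", 3),
                fovs_per_condition=d.get("fovs_per_condition", 4),
                timepoints_h=list(d.get("timepoints_h", default_timepoints())),
                optical=OpticalConfig.from_dict(d.get("optical", {})),
                recon=ReconstructionParams.from_dict(d.get("recon", {})),
                background=BackgroundParams.from_dict(d.get("background", {})),
                drymass=DryMassParams.from_dict(d.get("drymass", {})),
                scene_kwargs=dict(d.get("scene_kwargs", {})),
                master_seed=d.get("master_seed", 0),
                save_holograms=d.get("save_holograms", False),
                save_phase_maps=d.get("save_phase_maps", True),
                make_plots=d.get("make_plots", True),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid experiment config: {exc}") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        try:
            text = path.read_text()
            data = (
                json.loads(text)
                if path.suffix.lower() == ".json"
                else yaml.safe_load(text)
            )
        except (OSError, ValueError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
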