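"""Run configuration: YAML schema, validation, defaults.

Every default mirrors the published protocol values: 1 Å voxels, a 5 Å
protein shell, a 0.2 surface threshold, a 4 Å environment cutoff, a
500 ps / 3 Å stability rule, and a 20-40 ns window sampled every 10 ps
across 20 runs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

__all__ = ["RunConfig", "ConfigError", "load_validate_config", "dump_config"]


class ConfigError(ValueError):
    pass


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ProbeConfig(_StrictModel):
    preset: str = "vprobe"
    resname: str | None = None
    alignment_atoms: list[str] | None = None
    symmetry_mappings: list[list[str]] | None = None
    atoms: dict[str, list[float]] | None = None


class GridConfig(_StrictModel):
    spacing: float = Field(default=1.0, gt=0)
    margin: float = Field(default=8.0, gt=0)
    # optional point snapped to a voxel center (e.g. a known site of
    # interest, so it cannot straddle voxel faces)
    align_point: list[float] | None = None


class ThresholdConfig(_StrictModel):
    surface_theta: float = 0.2
    environment_cutoff: float = Field(default=4.0, gt=0)
    shell_cutoff: float = Field(default=5.0, gt=0)
    stability_lag_ps: float = Field(default=500.0, gt=0)
    stability_cutoff: float = Field(default=3.0, gt=0)


class ScheduleConfig(_StrictModel):
    t_start_ps: float = Field(default=20_000.0, ge=0)
    t_end_ps: float = Field(default=40_000.0, ge=0)
    interval_ps: float = Field(default=10.0, gt=0)

    @field_validator("t_end_ps")
    @classmethod
    def _window_ok(cls, v: float, info) -> float:
        start = info.data.get("t_start_ps")
        if start is not None and v < start:
            raise ValueError("t_end_ps must be >= t_start_ps")
        return v


class RunsConfig(_StrictModel):
    count: int = Field(default=20, ge=1)
    paths: list[str] = Field(default_factory=list)


class ProfileConfig(_StrictModel):
    margin: float = Field(default=8.0, gt=0)
    atom_selector: str = "CB"
    apply_stability_filter: bool = False


class RunConfig(_StrictModel):
    probe: ProbeConfig = Field(default_factory=ProbeConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    runs: RunsConfig = Field(default_factory=RunsConfig)
    profile: ProfileConfig = Field(default_factory=ProfileConfig)
    seed: int = 0


def load_validate_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; an empty (or absent) file yields all defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"{path}: top level must be a mapping")
            raw = loaded
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )
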