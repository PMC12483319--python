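"""Validated run configurations for the command-line interface.

Each pipeline stage has a pydantic model (unknown keys are rejected and
every offending key is named); ``validate_config`` loads a YAML/JSON
file into the right model based on its ``command`` field.
"""

from __future__ import annotations

import json
import os
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["validate_config", "RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Strict):
    shape: list[int] = [64, 128, 128]
    voxel_size: float = 1.554
    n_vesicles: int = 25
    vesicle_radius_range: list[float] = [16.0, 24.0]
    structures: list[str] = []
    membrane_contrast: float = 0.35
    noise_sd: float = 0.05
    min_gap_nm: float = 3.0
    max_retries: int = 1000


class SimulateConfig(_Strict):
    command: Literal["simulate"] = "simulate"
    out_dir: str
    phantom: PhantomSection = PhantomSection()
    shift_blur_sigma: float = 0.0
    shift_noise_scale: float = 0.0
    shift_contrast_gamma: float = 1.0
    seed: int = 0
    log_level: str = "INFO"


class TrainSection(_Strict):
    learning_rate: float = 1e-4
    iterations: int = 1000
    patch_shape: list[int] = [48, 48]
    batch_size: int = 4
    epoch_iterations: int = 100
    val_fraction: float = 0.1
    augment: bool = True


class ModelSection(_Strict):
    dimensionality: int = 2
    levels: int = 4
    initial_features: int = 32
    anisotropic_first_downsample: bool = False
    out_channels: list[str] = ["foreground", "boundary"]


class TrainCommandConfig(_Strict):
    command: Literal["train"] = "train"
    raw_paths: list[str]
    label_paths: list[str]
    checkpoint_out: str
    voxel_size: Optional[float] = None
    model: ModelSection = ModelSection()
    train: TrainSection = TrainSection()
    seed: int = 0
    log_level: str = "INFO"


class AdaptCommandConfig(_Strict):
    command: Literal["adapt"] = "adapt"
    pretrained: str
    target_paths: list[str]
    checkpoint_out: str
    voxel_size: Optional[float] = None
    t_c: float = 0.75
    alpha: float = 0.999
    iterations: int = 500
    patch_shape: list[int] = [48, 48]
    batch_size: int = 2
    learning_rate: float = 1e-4
    teacher_view: Literal["original", "augmented"] = "original"
    seed: int = 0
    log_level: str = "INFO"


_PRESETS = ("vesicles3d", "vesicles2d", "active_zone", "mitochondria", "ribbon", "compartments")


class SegmentCommandConfig(_Strict):
    command: Literal["segment"] = "segment"
    preset: Literal[_PRESETS] = "vesicles3d"
    in_path: str
    out_path: str
    checkpoint: Optional[str] = None
    oracle_labels: Optional[str] = None  # use oracle maps from labels instead of a model
    voxel_size: Optional[float] = None
    boundary_threshold: Optional[float] = None  # defaults from preset
    seed_distance: Optional[float] = None
    foreground_threshold: float = 0.5
    min_size: int = 500
    seed: int = 0
    log_level: str = "INFO"


class AnalyzeCommandConfig(_Strict):
    command: Literal["analyze"] = "analyze"
    vesicle_path: str
    structure_paths: dict[str, str] = {}
    compartment_path: Optional[str] = None
    out_table: str
    voxel_size: Optional[float] = None
    ribbon_assoc_max: float = 80.0
    mp_pd_max: float = 100.0
    mp_mem_max: float = 50.0
    docked_pd_max: float = 100.0
    docked_mem_max: float = 2.0
    seed: int = 0
    log_level: str = "INFO"


class EvaluateCommandConfig(_Strict):
    command: Literal["evaluate"] = "evaluate"
    seg_path: str
    gt_path: str
    out_table: str
    metric: Literal["f1", "dice", "sbd", "surface_dice"] = "f1"
    iou: float = 0.5
    tolerance: float = 1.0
    seed: int = 0
    log_level: str = "INFO"


class PipelineConfig(_Strict):
    command: Literal["pipeline"] = "pipeline"
    stages: list[dict]
    seed: int = 0
    log_level: str = "INFO"


RunConfig = Union[
    SimulateConfig,
    TrainCommandConfig,
    AdaptCommandConfig,
    SegmentCommandConfig,
    AnalyzeCommandConfig,
    EvaluateCommandConfig,
    PipelineConfig,
]

_BY_COMMAND = {
    "simulate": SimulateConfig,
    "train": TrainCommandConfig,
    "adapt": AdaptCommandConfig,
    "segment": SegmentCommandConfig,
    "analyze": AnalyzeCommandConfig,
    "evaluate": EvaluateCommandConfig,
    "pipeline": PipelineConfig,
}

_INPUT_PATH_FIELDS = {
    "train": ("raw_paths", "label_paths"),
    "adapt": ("pretrained", "target_paths"),
    "segment": ("in_path",),
    "analyze": ("vesicle_path",),
    "evaluate": ("seg_path", "gt_path"),
}


def _check_paths(cfg) -> None:
    for field_name in _INPUT_PATH_FIELDS.get(cfg.command, ()):
        value = getattr(cfg, field_name)
        paths = value if isinstance(value, list) else [value]
        for p in paths:
            if not os.path.exists(p):
                raise ConfigError(f"{cfg.command}: input path does not exist: {p}")


def parse_config(payload: dict) -> RunConfig:
    if "command" not in payload:
        raise ConfigError("config must declare a 'command'")
    cls = _BY_COMMAND.get(payload["command"])
    if cls is None:
        raise ConfigError(
            f"unknown command {payload['command']!r}; expected one of {sorted(_BY_COMMAND)}"
        )
    try:
        cfg = cls(**payload)
    except ValidationError as err:
        bad = "; ".join(
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in err.errors()
        )
        raise ConfigError(f"invalid {payload['command']} config: {bad}") from err
    if payload["command"] == "pipeline":
        cfg.stages = [parse_config(s).model_dump() for s in cfg.stages]
    return cfg


def validate_config(path, check_paths: bool = True) -> RunConfig:
    """Load and validate a YAML/JSON run config; fill defaults."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    cfg = parse_config(payload)
    if check_paths and cfg.command != "pipeline":
        _check_paths(cfg)
    return cfg
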