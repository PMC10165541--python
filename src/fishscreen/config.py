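"""Run configuration: typed stage parameters with strict key validation.

A run config is a YAML/JSON document with one section per pipeline stage.
Unknown keys are rejected at load time, and the config round-trips
losslessly through ``to_dict`` / ``from_dict``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from fishscreen.compartments import SegmentationParams
from fishscreen.spots import DetectionParams, PSFModel
from fishscreen.synthetic import (
    AnnotationSimConfig,
    NoiseModel,
    SimulationConfig,
)


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _build(cls, data: dict, path: str):
    """Instantiate a (nested) dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        target = _DATACLASS_FIELDS.get((cls, name))
        if name == "compartment_layout" and isinstance(value, (list, tuple)):
            kwargs[name] = tuple(
                _parse_primitive(v, f"{path}.{name}[{i}]")
                for i, v in enumerate(value)
            )
        elif target is not None and isinstance(value, dict):
            kwargs[name] = _build(target, value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in value
            )
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _parse_primitive(data, path: str):
    """Geometry primitive from a mapping; discriminated by its keys."""
    from fishscreen.synthetic import Ellipsoid, Tube

    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    keys = set(data) - {"label"}
    if keys == {"center", "radii"}:
        return Ellipsoid(
            label=data["label"],
            center=tuple(data["center"]),
            radii=tuple(data["radii"]),
        )
    if keys == {"start", "end", "radius"}:
        return Tube(
            label=data["label"],
            start=tuple(data["start"]),
            end=tuple(data["end"]),
            radius=float(data["radius"]),
        )
    raise ConfigError(f"{path}: not an ellipsoid or tube definition")


@dataclass(frozen=True)
class DetectStage:
    channel: str = "probe_a"
    psf: PSFModel = field(
        default_factory=lambda: PSFModel(sigma_lateral=0.13, sigma_axial=0.35)
    )
    params: DetectionParams = field(default_factory=DetectionParams)
    subtract_background: bool = True


@dataclass(frozen=True)
class SegmentStage:
    marker_channel: str = "marker"
    params: SegmentationParams = field(default_factory=SegmentationParams)


@dataclass(frozen=True)
class CompareStage:
    compartment: str = "nmj_axon_terminal"
    value: str = "n_single_mRNA"
    tail: str = "two"
    direction: str = "less"
    force_test: str | None = None


@dataclass(frozen=True)
class ScoreStage:
    genome_protein_coding: int = 13_900


@dataclass(frozen=True)
class SimulateStage:
    image: SimulationConfig | None = None
    annotation: AnnotationSimConfig | None = None


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    simulate: SimulateStage = field(default_factory=SimulateStage)
    detect: DetectStage = field(default_factory=DetectStage)
    segment: SegmentStage = field(default_factory=SegmentStage)
    compare: CompareStage = field(default_factory=CompareStage)
    score: ScoreStage = field(default_factory=ScoreStage)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data or {}, "config")

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


# nested-dataclass field registry used by the strict builder
_DATACLASS_FIELDS = {
    (RunConfig, "simulate"): SimulateStage,
    (RunConfig, "detect"): DetectStage,
    (RunConfig, "segment"): SegmentStage,
    (RunConfig, "compare"): CompareStage,
    (RunConfig, "score"): ScoreStage,
    (SimulateStage, "image"): SimulationConfig,
    (SimulateStage, "annotation"): AnnotationSimConfig,
    (DetectStage, "psf"): PSFModel,
    (DetectStage, "params"): DetectionParams,
    (SegmentStage, "params"): SegmentationParams,
    (SimulationConfig, "noise_model"): NoiseModel,
}


def load_run_config(path: str | Path | None) -> RunConfig:
    """Read a YAML or JSON run config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.from_dict(data)
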