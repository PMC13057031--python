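"""Build typed configuration objects from plain (YAML-loaded) mappings.

Config files carry a ``schema_version`` so future layouts can migrate; the
current version is 1.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses

from .classify import ClassifierParams
from .errors import ConfigError
from .pipeline import PipelineConfig
from .segment import SegmentationParams
from .simulate import DegradationRates, NoiseModel, SimulationConfig

SCHEMA_VERSION = 1


def _build(cls, data: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"{name}: unknown keys {sorted(unknown)}")
    return cls(**data)


def simulation_config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    data.pop("schema_version", None)
    if "degradation" in data and isinstance(data["degradation"], dict):
        data["degradation"] = _build(DegradationRates, data["degradation"],
                                     "degradation")
    if "noise" in data and isinstance(data["noise"], dict):
        data["noise"] = _build(NoiseModel, data["noise"], "noise")
    for key in ("field_size_px", "rbc_diameter_um", "mn_diameter_um"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return _build(SimulationConfig, data, "simulation")


def pipeline_config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported config schema_version {version}")
    if isinstance(data.get("segmentation"), dict):
        data["segmentation"] = _build(SegmentationParams, data["segmentation"],
                                      "segmentation")
    if isinstance(data.get("classifier"), dict):
        clf = dict(data["classifier"])
        if isinstance(clf.get("mn_focus_area_range_um2"), list):
            clf["mn_focus_area_range_um2"] = tuple(clf["mn_focus_area_range_um2"])
        data["classifier"] = _build(ClassifierParams, clf, "classifier")
    if isinstance(data.get("simulation"), dict):
        data["simulation"] = simulation_config_from_dict(data["simulation"])
    return _build(PipelineConfig, data, "pipeline")


def simulation_config_to_dict(config: SimulationConfig) -> dict:
    data = dataclasses.asdict(config)
    data["schema_version"] = SCHEMA_VERSION
    data["field_size_px"] = list(config.field_size_px)
    data["rbc_diameter_um"] = list(config.rbc_diameter_um)
    data["mn_diameter_um"] = list(config.mn_diameter_um)
    return data
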