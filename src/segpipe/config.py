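"""Single-file YAML pipeline configuration.

Sections: ``data``, ``preprocessing``, ``patches``, ``augmentation``,
``model``, ``training``, ``evaluation``.  Every field maps one-to-one onto
the corresponding spec dataclass; unknown keys raise a configuration error
rather than being silently dropped.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Any, Dict, Optional, Tuple

import yaml

from .augmentation import AugmentSpec
from .errors import ConfigurationError
from .model import UNetConfig
from .patching import PatchConfig
from .pipeline import BatchPlan, TrainSpec
from .preprocessing import PreprocSpec


@dataclasses.dataclass
class DataConfig:
    interface: str = "nifti"
    root: Optional[str] = None
    image_name: str = "imaging.nii.gz"
    seg_name: str = "segmentation.nii.gz"


@dataclasses.dataclass
class EvalConfig:
    mode: str = "kfold"
    k: Optional[int] = 3
    fraction: Optional[float] = None
    seed: int = 0


@dataclasses.dataclass
class PipelineConfig:
    data: DataConfig
    preprocessing: PreprocSpec
    patches: PatchConfig
    augmentation: AugmentSpec
    model: UNetConfig
    training: TrainSpec
    batch: BatchPlan
    evaluation: EvalConfig


def _build(cls, section: Dict[str, Any], name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ConfigurationError(
            f"unknown keys in config section {name!r}: {sorted(unknown)}"
        )
    kwargs = {}
    for key, value in section.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(raw: Dict[str, Any]) -> PipelineConfig:
    raw = dict(raw or {})
    known = {"data", "preprocessing", "patches", "augmentation", "model",
             "training", "batch", "evaluation"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    return PipelineConfig(
        data=_build(DataConfig, raw.get("data", {}), "data"),
        preprocessing=_build(PreprocSpec, raw.get("preprocessing", {}), "preprocessing"),
        patches=_build(PatchConfig, raw.get("patches", {}), "patches"),
        augmentation=_build(AugmentSpec, raw.get("augmentation", {}), "augmentation"),
        model=_build(UNetConfig, raw.get("model", {}), "model"),
        training=_build(TrainSpec, raw.get("training", {}), "training"),
        batch=_build(BatchPlan, raw.get("batch", {}), "batch"),
        evaluation=_build(EvalConfig, raw.get("evaluation", {}), "evaluation"),
    )


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def load_reference_config(name: str = "kits19_reference") -> PipelineConfig:
    """Load a configuration shipped with the package (documentation fixture)."""
    text = resources.files("segpipe.configs").joinpath(f"{name}.yaml").read_text()
    return config_from_dict(yaml.safe_load(text))
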