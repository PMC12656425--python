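"""Run configuration: YAML/JSON loading, validation, seed substreams.

A single ``RunConfig`` nests the per-module configurations.  Unknown
keys are rejected (typos should fail loudly, not silently fall back to
defaults), every sub-config validates its own invariants at
construction, and the effective configuration can be written back out
so a run directory is self-describing.

All randomness flows from one global seed through named substreams
(:func:`substream`), so any module's draws are reproducible in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import yaml

from voxfuse.contrastive import AugmentationConfig, EncoderConfig, PretrainConfig
from voxfuse.errors import ValidationError
from voxfuse.fusion import ClassifierConfig
from voxfuse.preprocessing import PreprocessConfig
from voxfuse.synth import ClassProfile, CohortSpec
from voxfuse.training import TrainingConfig
from voxfuse.attribution import ForestConfig


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    )


def substream_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2^31) for APIs that take one."""
    return int(substream(seed, name).integers(0, 2**31 - 1))


@dataclass
class RunConfig:
    """Top-level configuration nesting all module configs."""

    seed: int = 0
    out_dir: str = "runs/default"
    log_level: str = "INFO"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    forest: ForestConfig = field(default_factory=ForestConfig)


_NESTED = {
    "preprocess": PreprocessConfig,
    "encoder": EncoderConfig,
    "pretrain": PretrainConfig,
    "classifier": ClassifierConfig,
    "training": TrainingConfig,
    "cohort": CohortSpec,
    "forest": ForestConfig,
}


def _build(cls, payload: Dict[str, Any], context: str):
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(payload) - set(allowed)
    if unknown:
        raise ValidationError(f"unknown key(s) {sorted(unknown)} in {context}")
    kwargs = {}
    for key, value in payload.items():
        if cls is CohortSpec and key == "profiles":
            value = {int(k): ClassProfile(**v) for k, v in value.items()}
        elif cls is PretrainConfig and key == "augmentation":
            value = _build(AugmentationConfig, value, f"{context}.augmentation")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML or JSON; empty file -> all defaults."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ValidationError(f"cannot read config file {path}: {exc}") from exc
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text or "{}")
    payload = payload or {}
    if not isinstance(payload, dict):
        raise ValidationError(f"config root must be a mapping, got {type(payload)}")

    top_allowed = {f.name for f in fields(RunConfig)}
    unknown = set(payload) - top_allowed
    if unknown:
        raise ValidationError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs: Dict[str, Any] = {}
    for key, value in payload.items():
        if key in _NESTED:
            kwargs[key] = _build(_NESTED[key], value or {}, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def _to_plain(obj) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def save_config(cfg: RunConfig, path) -> None:
    """Write the effective configuration as YAML (round-trips via load)."""
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))
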