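"""Experiment configuration: nested schema, YAML/JSON loading, seeding.

A single global seed fans out to per-module seeds through a documented
splitter (CRC32 of the module name mixed into a ``SeedSequence``), so one
knob reproduces an entire experiment. A resolved copy of every config
(defaults filled in) is written next to each output.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .au_models import AUDetectorConfig
from .augmentation import AugmentationSpec
from .exceptions import InvalidInputError
from .pain_models import PainLSTMConfig, PainTransformerConfig
from .simulate import SimulationConfig


def derive_seed(global_seed: int, module: str) -> int:
    """Deterministic per-module seed below 2^31."""
    key = zlib.crc32(module.encode()) % (2 ** 31)
    ss = np.random.SeedSequence([int(global_seed), key])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class EvaluationSettings:
    au_folds: int = 3
    pain_folds: int = 10
    au_source: str = "ground8"
    window_length: int = 350
    window_stride: int | None = None
    frame_stride: int = 1
    threshold: float = 0.5


@dataclass
class ExperimentConfig:
    """Top-level experiment description mirroring each module's config."""

    seed: int = 0
    output_dir: str = "runs"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    au_detector: AUDetectorConfig = field(default_factory=AUDetectorConfig)
    intensity: AUDetectorConfig = field(
        default_factory=lambda: AUDetectorConfig(output_units=5))
    pain_transformer: PainTransformerConfig = field(
        default_factory=PainTransformerConfig)
    pain_lstm: PainLSTMConfig = field(default_factory=PainLSTMConfig)
    evaluation: EvaluationSettings = field(default_factory=EvaluationSettings)

    def __post_init__(self):
        # fan the global seed out to any section left at its default seed
        for name in ("simulation", "augmentation", "au_detector", "intensity",
                     "pain_transformer", "pain_lstm"):
            section = getattr(self, name)
            if getattr(section, "seed", None) == 0:
                section.seed = derive_seed(self.seed, name)


_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "augmentation": AugmentationSpec,
    "au_detector": AUDetectorConfig,
    "intensity": AUDetectorConfig,
    "pain_transformer": PainTransformerConfig,
    "pain_lstm": PainLSTMConfig,
    "evaluation": EvaluationSettings,
}


def _build_section(cls, obj: dict, path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(obj) - valid
    if unknown:
        raise InvalidInputError(
            f"unknown config key(s) {sorted(unknown)} at {path}")
    kwargs = dict(obj)
    if cls is SimulationConfig and "simulated_au_ids" in kwargs:
        kwargs["simulated_au_ids"] = tuple(kwargs["simulated_au_ids"])
    if cls is AugmentationSpec and "framing_scale" in kwargs:
        kwargs["framing_scale"] = tuple(kwargs["framing_scale"])
    return cls(**kwargs)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an ExperimentConfig from YAML or JSON; unknown keys rejected."""
    path = Path(path)
    text = path.read_text()
    obj = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if obj is None:
        obj = {}
    if not isinstance(obj, dict):
        raise InvalidInputError("config root must be a mapping")
    top_valid = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(obj) - top_valid
    if unknown:
        raise InvalidInputError(f"unknown config key(s) {sorted(unknown)} at <root>")
    kwargs = {}
    for key, value in obj.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise InvalidInputError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    return ExperimentConfig(**kwargs)


def resolved_dict(config: ExperimentConfig) -> dict:
    out = dataclasses.asdict(config)
    out["simulation"]["simulated_au_ids"] = list(out["simulation"]["simulated_au_ids"])
    out["augmentation"]["framing_scale"] = list(out["augmentation"]["framing_scale"])
    return out


def write_resolved(config: ExperimentConfig, directory: str | Path) -> Path:
    """Write the fully resolved config next to the run's outputs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "resolved_config.yaml"
    path.write_text(yaml.safe_dump(resolved_dict(config), sort_keys=False))
    return path
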