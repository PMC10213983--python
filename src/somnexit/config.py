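"""Run configuration: one YAML file covering every module, plus overrides.

The YAML mirrors the dataclass fields section-for-section::

    seed: 0
    out_dir: runs/demo
    model:
      preset: reduced            # or "default"
      efem: {eeg: {...}, eog: {...}, emg: {...}}
      exit: {eeg: {...}, eog: {...}, emg: {...}}
    train: {lr: 1.e-3, batch_size: 64, ...}
    synth: {n_epochs: 1500, ...}

Unknown keys are rejected with a field-level message.  Command-line
overrides use dotted paths (``train.lr=3e-4``) and take precedence over the
file, which takes precedence over defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .efem import EfemConfig
from .heads import EncoderConfig
from .model import ModelConfig
from .signals import SyntheticDatasetConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_run_config", "apply_overrides"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/out"
    verbosity: int = 1
    model: ModelConfig = field(default_factory=ModelConfig.reduced)
    train: TrainConfig = field(default_factory=lambda: TrainConfig.desk_scale())
    synth: SyntheticDatasetConfig = field(default_factory=SyntheticDatasetConfig)


_SECTION_KEYS = {"seed", "out_dir", "verbosity", "model", "train", "synth"}
_MOD_ALIAS = {"eeg": "EEG", "eog": "EOG", "emg": "EMG"}


def _build_dataclass(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in names:
            raise ValueError(f"unknown config key {path}.{key}")
        kwargs[key] = value
    return cls(**kwargs)


def _build_model(section: dict) -> ModelConfig:
    preset = section.get("preset", "reduced")
    if preset == "reduced":
        base = ModelConfig.reduced()
    elif preset == "default":
        base = ModelConfig()
    else:
        raise ValueError(f"unknown model.preset {preset!r}")
    efem = dict(base.efem)
    for mod_key, sub in (section.get("efem") or {}).items():
        mod = _MOD_ALIAS.get(mod_key.lower())
        if mod is None:
            raise ValueError(f"unknown config key model.efem.{mod_key}")
        efem[mod] = _build_dataclass(
            EfemConfig,
            {**dataclasses.asdict(efem[mod]), **sub},
            f"model.efem.{mod_key}",
        )
    encoder = dict(base.encoder)
    for mod_key, sub in (section.get("exit") or {}).items():
        mod = _MOD_ALIAS.get(mod_key.lower())
        if mod is None:
            raise ValueError(f"unknown config key model.exit.{mod_key}")
        encoder[mod] = _build_dataclass(
            EncoderConfig,
            {**dataclasses.asdict(encoder[mod]), **sub},
            f"model.exit.{mod_key}",
        )
    length = section.get("input_length", base.input_length)
    return ModelConfig(input_length=length, efem=efem, encoder=encoder)


def load_run_config(path: str | None = None,
                    overrides: list[str] | None = None) -> RunConfig:
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data = apply_overrides(data, overrides or [])
    for key in data:
        if key not in _SECTION_KEYS:
            raise ValueError(f"unknown config key {key}")
    cfg = RunConfig()
    cfg.seed = int(data.get("seed", cfg.seed))
    cfg.out_dir = str(data.get("out_dir", cfg.out_dir))
    cfg.verbosity = int(data.get("verbosity", cfg.verbosity))
    if "model" in data:
        cfg.model = _build_model(data["model"] or {})
    if "train" in data:
        base = dataclasses.asdict(cfg.train)
        cfg.train = _build_dataclass(
            TrainConfig, {**base, **(data["train"] or {})}, "train"
        )
    if "synth" in data:
        base = dataclasses.asdict(cfg.synth)
        merged = {**base, **(data["synth"] or {})}
        if isinstance(merged.get("class_proportions"), list):
            merged["class_proportions"] = tuple(merged["class_proportions"])
        if isinstance(merged.get("tier_proportions"), list):
            merged["tier_proportions"] = tuple(merged["tier_proportions"])
        cfg.synth = _build_dataclass(SyntheticDatasetConfig, merged, "synth")
    return cfg


def apply_overrides(data: dict, overrides: list[str]) -> dict:
    """Apply ``a.b.c=value`` overrides on top of the loaded mapping."""
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form key=value")
        dotted, raw = item.split("=", 1)
        value = yaml.safe_load(raw)
        node = data
        parts = dotted.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
            if not isinstance(node, dict):
                raise ValueError(f"cannot override through scalar at {p}")
        node[parts[-1]] = value
    return data
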