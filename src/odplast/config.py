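"""Run configuration: YAML loading, validation, parameter hashing.

A config file holds flat key-value overrides grouped in sections
([model], [plasticity], [protocol], [outputs]); anything not given
falls back to the reference defaults.  Unknown keys are rejected with
the offending name, and the fully resolved parameter set is persisted
with every run so outputs are reproducible bit-exactly from the file.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import Deprivation, EEMode, ModelParams, Stage

__all__ = ["RunConfig", "load_config", "save_config", "resolved_dict", "param_hash"]

# section -> (target dataclass attribute path on ModelParams)
_SECTION_PATHS = {
    "gain": "gain",
    "eyemap": "eyemap",
    "drive": "drive",
    "ee": "ee",
    "ei": "ei",
    "ie": "ie",
    "simplified": "simplified",
    "network": "network",
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    model: str = "simplified"            # simplified | network
    rule: EEMode = EEMode.DOUBLE
    deprivation: Deprivation = Deprivation.MD_CL
    stage: Stage = Stage.CP
    seed: int = 1
    out_dir: str = "results"
    stride_ms: int = 50                  # trajectory downsampling
    params: ModelParams = field(default_factory=ModelParams)

    def validate(self) -> None:
        if self.model not in ("simplified", "network"):
            raise ValueError(f"unknown model variant: {self.model!r}")
        if self.stride_ms <= 0:
            raise ValueError("stride_ms must be positive")
        self.params.validate()


def _apply_overrides(obj, overrides: dict, path: str):
    for key, value in overrides.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown parameter {path}.{key}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            raise KeyError(f"{path}.{key} is a section, not a value")
        if isinstance(current, EEMode):
            value = EEMode(value)
        elif isinstance(current, bool):
            if not isinstance(value, bool):
                raise TypeError(f"{path}.{key} expects a boolean")
        elif isinstance(current, (int, float)):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise TypeError(f"{path}.{key} expects a number")
        setattr(obj, key, type(current)(value) if not isinstance(current, EEMode)
                else value)


def load_config(path: str | Path | None = None,
                data: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file (or a pre-parsed mapping)."""
    if data is None:
        if path is None:
            data = {}
        else:
            path = Path(path)
            if not path.exists():
                raise FileNotFoundError(str(path))
            data = yaml.safe_load(path.read_text()) or {}
    cfg = RunConfig()
    top = dict(data)

    model_section = top.pop("model", {}) or {}
    for key in ("variant", "rule"):
        if key in model_section:
            val = model_section.pop(key)
            if key == "variant":
                cfg.model = str(val)
            else:
                cfg.rule = EEMode(val)
    if model_section:
        raise KeyError(f"unknown key model.{next(iter(model_section))}")

    protocol = top.pop("protocol", {}) or {}
    if "deprivation" in protocol:
        cfg.deprivation = Deprivation(protocol.pop("deprivation"))
    if "stage" in protocol:
        cfg.stage = Stage(protocol.pop("stage"))
    if "seed" in protocol:
        cfg.seed = int(protocol.pop("seed"))
    if protocol:
        raise KeyError(f"unknown key protocol.{next(iter(protocol))}")

    outputs = top.pop("outputs", {}) or {}
    if "dir" in outputs:
        cfg.out_dir = str(outputs.pop("dir"))
    if "stride_ms" in outputs:
        cfg.stride_ms = int(outputs.pop("stride_ms"))
    if outputs:
        raise KeyError(f"unknown key outputs.{next(iter(outputs))}")

    plasticity = top.pop("plasticity", {}) or {}
    for section, overrides in list(plasticity.items()):
        if section not in ("ee", "ei", "ie"):
            raise KeyError(f"unknown section plasticity.{section}")
        _apply_overrides(getattr(cfg.params, section), overrides or {},
                         f"plasticity.{section}")

    for section, overrides in top.items():
        if section not in _SECTION_PATHS:
            raise KeyError(f"unknown section {section}")
        _apply_overrides(getattr(cfg.params, _SECTION_PATHS[section]),
                         overrides or {}, section)

    cfg.validate()
    return cfg


def resolved_dict(cfg: RunConfig) -> dict:
    """Fully resolved, JSON-serializable parameter set."""
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, (EEMode, Deprivation, Stage)):
            return obj.value
        return obj
    return {
        "model": cfg.model,
        "rule": cfg.rule.value,
        "deprivation": cfg.deprivation.value,
        "stage": cfg.stage.value,
        "seed": cfg.seed,
        "stride_ms": cfg.stride_ms,
        "params": enc(cfg.params),
    }


def param_hash(cfg: RunConfig) -> str:
    """Stable short hash of the resolved configuration."""
    blob = json.dumps(resolved_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = resolved_dict(cfg)
    payload = {
        "model": {"variant": d["model"], "rule": d["rule"]},
        "protocol": {"deprivation": d["deprivation"], "stage": d["stage"],
                     "seed": d["seed"]},
        "outputs": {"dir": cfg.out_dir, "stride_ms": d["stride_ms"]},
        **{k: v for k, v in d["params"].items()
           if k in _SECTION_PATHS and isinstance(v, dict)},
        "plasticity": {k: d["params"][k] for k in ("ee", "ei", "ie")},
    }
    for k in ("ee", "ei", "ie"):
        payload.pop(k, None)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
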