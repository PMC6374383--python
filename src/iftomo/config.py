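"""Pipeline configuration: defaults, YAML loading, strict validation.

The resolved configuration (defaults merged with overrides) is serialized
next to the outputs of every run so that any run can be re-executed from
its ``run.json`` alone. Unknown keys are rejected up front, before any
stage does work.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phantom import PhantomConfig


class ConfigError(ValueError):
    """Invalid pipeline configuration (unknown key, bad value)."""


@dataclass
class RegisterParams:
    channel: str = "DAPI"
    reference_index: int = 0
    max_rotation: float = 10.0
    max_translation: float | None = None
    angle_step: float = 0.5
    confidence_floor: float = 0.1


@dataclass
class StitchParams:
    blend: str = "feather"
    search_radius: int = 5
    refine: bool = True


@dataclass
class QuantifyParams:
    channel: str = "DAPI"
    threshold: float | str = "otsu"
    min_volume_voxels: int | None = None  # default: sphere of min nucleus radius
    lrc_channel: str = "GFP"
    lrc_floor: float = 1.0
    bin_edges: tuple[float, ...] = (0.0, 100.0, 200.0, 255.0)


ALL_STAGES = ("simulate", "stitch", "align", "assemble", "quantify")


@dataclass
class PipelineConfig:
    """Full configuration of an end-to-end run."""

    outdir: str = "iftomo_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    log_level: str = "INFO"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    register: RegisterParams = field(default_factory=RegisterParams)
    stitch: StitchParams = field(default_factory=StitchParams)
    quantify: QuantifyParams = field(default_factory=QuantifyParams)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        self.phantom.validate()
        if self.stitch.blend not in ("feather", "overwrite"):
            raise ConfigError(f"unknown blend mode {self.stitch.blend!r}")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["phantom"] = self.phantom.as_dict()
        d["quantify"]["bin_edges"] = list(self.quantify.bin_edges)
        return d


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown key(s) at {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if name == "phantom":
            value = _build(PhantomConfig, value or {}, f"{path}.phantom")
        elif name == "register":
            value = _build(RegisterParams, value or {}, f"{path}.register")
        elif name == "stitch":
            value = _build(StitchParams, value or {}, f"{path}.stitch")
        elif name == "quantify":
            value = _build(QuantifyParams, value or {}, f"{path}.quantify")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML (or JSON) config file, apply overrides, validate."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data)}")
    if overrides:
        data = _merge(data, overrides)
    cfg = _build(PipelineConfig, data, "config")
    cfg.validate()
    return cfg


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def save_run_record(config: PipelineConfig, path, timings: dict, extra: dict | None = None):
    """Write run.json: resolved config + versions + per-stage timings."""
    import iftomo

    record = {
        "config": config.as_dict(),
        "seed": config.seed,
        "versions": {"iftomo": iftomo.__version__},
        "timings_s": timings,
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2))
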