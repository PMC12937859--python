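"""Pipeline configuration: YAML round-trip and per-stage seed derivation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .preprocess import PreprocessConfig
from .gate import DetectorConfig
from .cascade import TrainConfig
from .synthetic import SynthConfig

__all__ = ["PipelineConfig", "load_config", "save_config", "derive_seed"]

_GOLDEN = 0x9E3779B97F4A7C15
_MASK = (1 << 64) - 1

#: fixed stage indices for seed fan-out
STAGE_IDS = {"simulate": 1, "calibrate": 2, "train": 3, "gate": 4, "evaluate": 5}


def derive_seed(global_seed: int, stage: str) -> int:
    """SplitMix64-style fan-out: one master seed, independent stage seeds.

    z = (seed + i * golden) is finalized by the SplitMix64 mixer; the
    result is reduced below 2^31 so any RNG accepts it. Stages are
    therefore reproducible in isolation.
    """
    i = STAGE_IDS.get(stage)
    if i is None:
        raise KeyError(f"unknown stage {stage!r}; one of {sorted(STAGE_IDS)}")
    z = (global_seed + i * _GOLDEN) & _MASK
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    z = z ^ (z >> 31)
    return int(z % (1 << 31))


@dataclass
class PipelineConfig:
    """All stage configurations plus the global seed and workdir."""

    seed: int = 20260128
    workdir: str = "lfpgate_run"
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def seeded(self) -> "PipelineConfig":
        """Propagate the global seed into the stage configs."""
        self.synth.seed = derive_seed(self.seed, "simulate")
        self.train.seed = derive_seed(self.seed, "train")
        return self


_SECTIONS = {"synth": SynthConfig, "preprocess": PreprocessConfig,
             "detector": DetectorConfig, "train": TrainConfig}


def _build(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    # YAML turns tuples into lists; coerce back where the dataclass expects them
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list) and "tuple" in str(f.type):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config; unknown keys anywhere are rejected by name."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    top_known = {"seed", "workdir", *_SECTIONS}
    unknown = set(data) - top_known
    if unknown:
        raise KeyError(f"unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(
        seed=int(data.get("seed", PipelineConfig.seed)),
        workdir=str(data.get("workdir", PipelineConfig.workdir)),
    )
    for name, cls in _SECTIONS.items():
        if name in data and data[name] is not None:
            setattr(cfg, name, _build(cls, data[name], name))
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = {
        "seed": cfg.seed,
        "workdir": cfg.workdir,
        **{name: asdict(getattr(cfg, name)) for name in _SECTIONS},
    }
    # tuples are not native YAML; store as lists (load_config restores them)
    def listify(obj):
        if isinstance(obj, dict):
            return {k: listify(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj
    Path(path).write_text(yaml.safe_dump(listify(data), sort_keys=False))
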