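"""Declarative pipeline configuration with lossless YAML round-trip.

Every numeric constant the method depends on lives here with its
default, so a generated config file is a complete, auditable statement
of the analysis settings: 2500 Hz working rate, 0.1 s segmentation
window, 50 ms merge distance, pre-emphasis 0.95, medium-time window
M = 2, the 1/15 power law, Adam at (0.001, 0.9, 0.999), variance
threshold 0.05, selection target 212, and the boosted-tree settings
600/7/1/1/3/0.01.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml

from .deep_features import CnnSpec
from .fusion_classify import BoostConfig
from .pncc import PnccConfig


@dataclass
class SegmentationConfig:
    window_s: float = 0.1
    weight: float = 5.0
    n_bins: int = 50
    merge_ms: float = 50.0
    spread_direction: str = "below"
    refine: bool = True
    normalize_amplitude: bool = True


@dataclass
class SelectionConfig:
    variance_threshold: float = 0.05
    target_dim: int = 212


@dataclass
class PipelineConfig:
    working_rate: int = 2500
    seed: int = 0
    use_deep_features: bool = False
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    pncc: PnccConfig = field(default_factory=PnccConfig)
    cnn: CnnSpec = field(default_factory=CnnSpec)
    boost: BoostConfig = field(default_factory=BoostConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    split_fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(_as_plain(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        return _from_plain(cls, data)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _as_plain(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        nested = None
        if f.default_factory is not dataclasses.MISSING:
            probe = f.default_factory()
            if dataclasses.is_dataclass(probe):
                nested = type(probe)
        if nested is not None:
            kwargs[f.name] = _from_plain(nested, value)
        elif isinstance(value, list):
            kwargs[f.name] = tuple(value)
        else:
            kwargs[f.name] = value
    return cls(**kwargs)
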