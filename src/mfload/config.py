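"""YAML pipeline configuration.

A :class:`PipelineConfig` gathers every stage's parameters plus the seed
list; it round-trips losslessly through YAML, and every pipeline run
writes its resolved configuration next to its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .decode import DecoderConfig
from .ersp import ERSPConfig
from .preprocess import PreprocessConfig
from .simulate import GeneratorConfig


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    ersp: ERSPConfig = field(default_factory=ERSPConfig)
    seeds: tuple[int, ...] = (0,)
    depth_jitter_sd: float = 0.0

    def __post_init__(self):
        self.seeds = tuple(int(s) for s in self.seeds)


def _to_plain(obj):
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _coerce(cls, data: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def to_yaml(cfg: PipelineConfig, path: str | Path | None = None) -> str:
    doc = {k: _to_plain(v) for k, v in asdict(cfg).items()}
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def from_yaml(source: str | Path) -> PipelineConfig:
    """Build a config from a YAML file path or a YAML string."""
    p = Path(source)
    text = p.read_text() if p.exists() else str(source)
    doc = yaml.safe_load(text) or {}
    return PipelineConfig(
        generator=_coerce(GeneratorConfig, doc.get("generator", {})),
        preprocess=_coerce(PreprocessConfig, doc.get("preprocess", {})),
        decoder=_coerce(DecoderConfig, doc.get("decoder", {})),
        ersp=_coerce(ERSPConfig, doc.get("ersp", {})),
        seeds=tuple(doc.get("seeds", (0,))),
        depth_jitter_sd=float(doc.get("depth_jitter_sd", 0.0)),
    )
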