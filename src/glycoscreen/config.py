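"""Pipeline configuration: defaults, YAML loading, strict validation.

Precedence is built-in defaults < YAML file < explicit overrides (CLI
flags). Unknown keys are rejected rather than ignored so a typo cannot
silently fall back to a default. Every default equals the screening
protocol's printed value where one exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .chemcore import (
    Adduct,
    FEATURE_ADDUCTS,
    GlycoShift,
    IDENTIFICATION_ADDUCTS,
    PoolingConfig,
)
from .quant import XicConfig
from .scoring import ScoringConfig
from .specproc import PreprocessConfig
from .synth import SynthConfig

__all__ = ["PipelineConfig", "load_config"]


def _build(cls, data: Mapping[str, Any], context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {context!r} block: {sorted(unknown)}")
    return cls(**data)


def _adducts(entries: list[dict], context: str) -> tuple[Adduct, ...]:
    out = []
    labels = set()
    for e in entries:
        a = _build(Adduct, e, context)
        if a.label in labels:
            raise ValueError(f"duplicate adduct label {a.label!r} in {context}")
        labels.add(a.label)
        out.append(a)
    return tuple(out)


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    xic: XicConfig = field(default_factory=XicConfig)
    pooling: PoolingConfig = field(default_factory=PoolingConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    shift: GlycoShift = field(default_factory=GlycoShift)
    feature_adducts: tuple[Adduct, ...] = FEATURE_ADDUCTS
    identification_adducts: tuple[Adduct, ...] = IDENTIFICATION_ADDUCTS
    precursor_tol: float = 0.003  # Da, MS2 feature admission window
    seed: int = 0
    blacklist: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        def plain(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {
                    f.name: plain(getattr(obj, f.name))
                    for f in fields(obj)
                }
            if isinstance(obj, tuple):
                return [plain(o) for o in obj]
            return obj

        return plain(self)

    def dump(self, path: str | Path) -> None:
        """Write the effective configuration next to outputs, for provenance."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_BLOCKS = {
    "preprocess": PreprocessConfig,
    "scoring": ScoringConfig,
    "xic": XicConfig,
    "pooling": PoolingConfig,
    "synth": SynthConfig,
    "shift": GlycoShift,
}


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> PipelineConfig:
    """Defaults, then the YAML file, then explicit overrides.

    ``overrides`` maps dotted keys (e.g. ``"scoring.decision_threshold"``)
    or top-level keys to values; None values are ignored so optional CLI
    flags can be passed straight through.
    """
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)

    kwargs: dict[str, Any] = {}
    top_allowed = {f.name for f in fields(PipelineConfig)}
    for key, value in data.items():
        if key not in top_allowed:
            raise ValueError(f"unknown top-level config key {key!r}")
        if key in _BLOCKS:
            kwargs[key] = _build(_BLOCKS[key], value, key)
        elif key in ("feature_adducts", "identification_adducts"):
            kwargs[key] = _adducts(value, key)
        elif key == "blacklist":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    config = PipelineConfig(**kwargs)

    for dotted, value in (overrides or {}).items():
        if value is None:
            continue
        if "." in dotted:
            block, attr = dotted.split(".", 1)
            target = getattr(config, block)
            if not hasattr(target, attr):
                raise ValueError(f"unknown override {dotted!r}")
            setattr(target, attr, value)
        else:
            if not hasattr(config, dotted):
                raise ValueError(f"unknown override {dotted!r}")
            setattr(config, dotted, value)
    return config
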