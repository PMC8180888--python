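"""YAML pipeline configuration with strict validation.

One ``PipelineConfig`` bundles every stage's parameters: scene geometry,
camera-emulation settings, the three layers' neuron/plasticity
constants (the published set by default), delay lines, readout scoring
and analysis options. Unknown keys are rejected on load so typos fail
loudly, and a stable content hash stamps derived artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

from .scenes import SceneConfig, LaunchRanges
from .frontend import FrontendConfig
from .network import LayerParams, DelayConfig, published_layer_params

__all__ = ["PipelineConfig", "ReadoutOptions", "AnalysisOptions",
           "load_config", "save_config", "config_hash"]

CONFIG_VERSION = 1


@dataclass(frozen=True)
class ReadoutOptions:
    score_tau: float | None = 0.5     # s; None disables the leak
    score_kernel: str = "gaussian"    # or "triangular"
    min_sigma: float = 1.0            # px floor on the bump width
    percentages: tuple = (15, 30, 45, 60, 75, 90)


@dataclass(frozen=True)
class AnalysisOptions:
    smooth_deg: int = 5               # boxcar for preferred-direction peaks
    dn_threshold: float | None = None  # None: scale 6 px by resolution
    n_permutations: int = 1000
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    launch: LaunchRanges = field(default_factory=LaunchRanges)
    frontend: FrontendConfig = field(default_factory=FrontendConfig)
    layers: list[LayerParams] = field(default_factory=published_layer_params)
    delays: DelayConfig = field(default_factory=DelayConfig)
    readout: ReadoutOptions = field(default_factory=ReadoutOptions)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    n_trajectories: int = 297
    split_fraction: float = 0.70
    epochs_per_layer: int = 1
    seed: int = 0
    version: int = CONFIG_VERSION


_SECTIONS = {
    "scene": SceneConfig,
    "launch": LaunchRanges,
    "frontend": FrontendConfig,
    "delays": DelayConfig,
    "readout": ReadoutOptions,
    "analysis": AnalysisOptions,
}
_SCALARS = {"n_trajectories", "split_fraction", "epochs_per_layer",
            "seed", "version"}


def _build(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    # YAML lists come back as lists; tuples where the dataclass expects them
    coerced = {k: tuple(v) if isinstance(v, list) else v
               for k, v in data.items()}
    return cls(**coerced)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(_SECTIONS) | _SCALARS | {"layers"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name] or {}, name)
    if "layers" in raw:
        kwargs["layers"] = [_build(LayerParams, row, f"layers[{i}]")
                            for i, row in enumerate(raw["layers"])]
    for name in _SCALARS:
        if name in raw:
            kwargs[name] = raw[name]
    return PipelineConfig(**kwargs)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the full configuration content."""
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
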