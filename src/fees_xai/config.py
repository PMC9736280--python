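"""YAML configuration shared by the command-line workflows.

One file holds optional sections ``scene``, ``sampler``, ``net``, ``train``,
``postprocess`` and ``timeline``; each section overrides the corresponding
dataclass defaults.  Unknown keys raise, so typos surface immediately.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .preprocess import SamplerConfig
from .synthetic import SceneConfig
from .unet import NetConfig, TrainConfig

__all__ = ["PipelineConfig", "load_config"]

_SECTION_TYPES = {
    "scene": SceneConfig,
    "sampler": SamplerConfig,
    "net": NetConfig,
    "train": TrainConfig,
}

_DEFAULT_POSTPROCESS = {"threshold": 0.5, "connectivity": 8}
_DEFAULT_TIMELINE = {"min_consecutive": 3, "min_pixels": 1}


class PipelineConfig:
    def __init__(self, raw: dict[str, Any] | None = None) -> None:
        raw = dict(raw or {})
        self.sections: dict[str, Any] = {}
        for name, cls in _SECTION_TYPES.items():
            kwargs = raw.pop(name, {}) or {}
            tuple_fields = {
                "image_size", "glottis_size_range", "bolus_size_range",
                "blur_sigma_range", "patch_size",
            }
            kwargs = {k: tuple(v) if k in tuple_fields and isinstance(v, list) else v
                      for k, v in kwargs.items()}
            self.sections[name] = cls(**kwargs)
        self.postprocess = {**_DEFAULT_POSTPROCESS, **(raw.pop("postprocess", {}) or {})}
        self.timeline = {**_DEFAULT_TIMELINE, **(raw.pop("timeline", {}) or {})}
        if raw:
            raise ValueError(f"unknown config sections: {sorted(raw)}")

    @property
    def scene(self) -> SceneConfig:
        return self.sections["scene"]

    @property
    def sampler(self) -> SamplerConfig:
        return self.sections["sampler"]

    @property
    def net(self) -> NetConfig:
        return self.sections["net"]

    @property
    def train(self) -> TrainConfig:
        return self.sections["train"]

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Return a copy with every section's seed replaced."""
        import dataclasses

        cfg = PipelineConfig()
        cfg.sections = {
            name: dataclasses.replace(sec, seed=seed) if hasattr(sec, "seed") else sec
            for name, sec in self.sections.items()
        }
        cfg.postprocess = dict(self.postprocess)
        cfg.timeline = dict(self.timeline)
        return cfg


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    return PipelineConfig(raw)
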