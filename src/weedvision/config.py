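"""Pipeline configuration: defaults, YAML loading, validation."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import SegmentationConfig

logger = logging.getLogger("weedvision")

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Every tunable of the detection pipeline in one place.

    Defaults are the published operating point of the method: NEG green
    coefficient 2.8; segmentation limits 20% / 0.5% (alternate 5%); at most
    30 threshold adjustments; maximum weed size 300 px; crop decision at
    network score 0.5.
    """

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    neg_coeff: float = 2.8
    max_weed_size: int = 300
    decision_threshold: float = 0.5
    size_rule: str = "override_weed"   # or "force_crop"
    extent_mode: str = "bbox"          # or "feret"
    min_region_area: int = 5
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.neg_coeff <= 0:
            raise ValueError("neg_coeff must be positive")
        if self.max_weed_size < 1:
            raise ValueError("max_weed_size must be >= 1")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.size_rule not in ("override_weed", "force_crop"):
            raise ValueError(f"unknown size_rule {self.size_rule!r}")
        if self.extent_mode not in ("bbox", "feret"):
            raise ValueError(f"unknown extent_mode {self.extent_mode!r}")


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; missing fields keep their defaults.

    Unknown keys and out-of-range values raise; the fully resolved
    configuration is echoed to the package logger.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")

    seg_keys = {f.name for f in dataclasses.fields(SegmentationConfig)}
    top_keys = {f.name for f in dataclasses.fields(PipelineConfig)} - {"segmentation"}

    seg_kwargs = {}
    if "segmentation" in data:
        sub = data.pop("segmentation")
        if not isinstance(sub, dict):
            raise ValueError("'segmentation' must be a mapping")
        unknown = set(sub) - seg_keys
        if unknown:
            raise ValueError(f"unknown segmentation keys: {sorted(unknown)}")
        seg_kwargs = sub
    # segmentation fields may also be given at top level, flat style
    for k in list(data):
        if k in seg_keys:
            seg_kwargs[k] = data.pop(k)
    unknown = set(data) - top_keys
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    cfg = PipelineConfig(segmentation=SegmentationConfig(**seg_kwargs), **data)
    logger.info("resolved config: %s", cfg)
    return cfg
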