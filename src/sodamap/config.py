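"""Run configuration: YAML file merged with command-line overrides."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .coupling import RingSpec
from .detection import DetectionParams
from .masking import HKParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Validated parameters for a single or batch pipeline run.

    ``mode`` selects the input regime: ``image`` (TIFF; spots detected by
    wavelet filtering, mask segmented from a counterstain channel unless
    ``mask_file`` is given) or ``localizations`` (SMLM CSV; points are used
    as-is and ``mask_file`` is mandatory).
    """

    mode: str = "image"
    ch1: int | str = 0
    ch2: int | str = 1
    mask_channel: int | None = 2
    mask_file: str | None = None
    pixel_size_nm: float = 100.0
    rings: str = "0:300:30"
    alpha: float = 0.05
    resamples: int = 500
    seed: int = 0
    both: bool = False
    out_dir: str = "sodamap_out"
    detection: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    column_map: dict | None = None
    loc_units: str = "nm"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, **overrides)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], **overrides: Any) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(raw)
        merged.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**merged)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("image", "localizations"):
            raise ValueError("mode must be 'image' or 'localizations'")
        if self.mode == "image" and self.mask_channel is None and not self.mask_file:
            raise ValueError(
                "image mode needs a mask channel or an external mask file"
            )
        if self.mode == "localizations" and not self.mask_file:
            raise ValueError("localization mode needs an external mask file")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.resamples < 2:
            raise ValueError("resamples must be >= 2")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        # these raise on invalid blocks
        self.ring_spec()
        self.detection_params()
        self.segmentation_params()

    def ring_spec(self) -> RingSpec:
        return RingSpec.from_string(self.rings)

    def detection_params(self) -> DetectionParams:
        block = dict(self.detection)
        if "scales" in block:
            block["scales"] = frozenset(block["scales"])
        return DetectionParams(**block)

    def segmentation_params(self) -> HKParams:
        return HKParams(**self.segmentation)
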