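"""Run configuration: resolution of presets, YAML round-trip, provenance.

A RunConfig is the complete, validated parameter set of a batch run; it
is serialized next to every batch output so the run can be reproduced
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields, replace
from pathlib import Path

import yaml

from .segmentation import SegmentationConfig, PRESETS


@dataclass
class RunConfig:
    """Everything a batch run needs, resolvable from preset + overrides."""

    space: str = "lab"
    preset: str | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    voi_log_base: float | None = None     # None = natural log
    averaging: str = "per-image"          # or "pooled"
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.space not in ("lab", "hsv", "rgb"):
            raise ValueError(f"unknown color space {self.space!r}")
        if self.averaging not in ("per-image", "pooled"):
            raise ValueError("averaging must be 'per-image' or 'pooled'")
        self.segmentation = replace(self.segmentation, space=self.space)

    def as_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        seg_keys = {f.name for f in fields(SegmentationConfig)}
        seg_dict = d.pop("segmentation", {})
        # tolerate flat files: segmentation keys at top level
        for k in list(d.keys()):
            if k in seg_keys and k != "space":
                seg_dict[k] = d.pop(k)
        preset = d.get("preset")
        if preset is not None:
            if preset not in PRESETS:
                raise ValueError(f"unknown preset {preset!r}; "
                                 f"available: {sorted(PRESETS)}")
            base = asdict(PRESETS[preset])
            base.update(seg_dict)
            seg_dict = base
        seg_dict.pop("space", None)
        seg = SegmentationConfig(space=d.get("space", "lab"), **seg_dict)
        known = {f.name for f in fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(segmentation=seg, **{k: v for k, v in d.items() if k != "segmentation"})

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)
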