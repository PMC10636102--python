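"""Pipeline configuration blocks, YAML round-trip and provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from itmt.segmentation import SegmentationConfig, TverskyParams


@dataclass
class PreprocessConfig:
    target_mm: float = 1.0
    median_radius: int = 1
    nbins: int = 256
    p_lo: float = 0.5
    p_hi: float = 99.5


@dataclass
class SliceSelectionConfig:
    thickness_mm: float = 5.0       # MIP slab thickness
    input_size: int = 256           # model input resolution
    band: tuple[int, int] | None = None  # candidate index range; None = central third
    stride: int = 2
    epochs: int = 30
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0
    dispersion_warn_mm: float = 4.0  # craniocaudal tolerance before warning


@dataclass
class SegmentationTrainConfig:
    epochs: int = 30
    lr: float = 0.2
    seed: int = 0


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    slice_selection: SliceSelectionConfig = field(default_factory=SliceSelectionConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    segmentation_train: SegmentationTrainConfig = field(default_factory=SegmentationTrainConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @staticmethod
    def from_yaml(src) -> "PipelineConfig":
        if isinstance(src, str) and "\n" in src:
            payload = yaml.safe_load(src)
        else:
            with open(src) as fh:
                payload = yaml.safe_load(fh)
        payload = payload or {}
        seg = payload.get("segmentation", {})
        tv = seg.pop("tversky", {}) if isinstance(seg, dict) else {}
        band = payload.get("slice_selection", {}).get("band")
        if band is not None:
            payload["slice_selection"]["band"] = tuple(band)
        return PipelineConfig(
            preprocess=PreprocessConfig(**payload.get("preprocess", {})),
            slice_selection=SliceSelectionConfig(**payload.get("slice_selection", {})),
            segmentation=SegmentationConfig(tversky=TverskyParams(**tv), **seg),
            segmentation_train=SegmentationTrainConfig(**payload.get("segmentation_train", {})),
            seed=int(payload.get("seed", 0)),
        )

    def hash(self) -> str:
        """Stable provenance hash: changes iff any config value changes."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
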