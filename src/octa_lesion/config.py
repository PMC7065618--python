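"""Pipeline configuration: every algorithm constant in one place.

Defaults reproduce the published processing constants: 0.3 mm depth
window, 3x3x3 median kernel, vesselness scales 1-5, 2.5 x 2.5 x 0.3 mm
ROIs with 30% overlap, lesion-presence limit 4e-5 on the VD standard
deviation, superficial-lesion threshold at 75% of the map maximum,
nodular iterative threshold starting 20% above the nonzero minimum and
growing by 30% per step, and a disk structuring element of radius 20 px
for mask refinement.

Configs serialize loss-free to/from nested dicts (YAML/JSON); unknown
keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Tuple

from .preprocess import FrangiConfig


def _from_dict(cls, d: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in d:
            continue
        val = d[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            val = _from_dict(f.type, val)
        kwargs[f.name] = val
    return cls(**kwargs)


@dataclass
class PreprocessConfig:
    window_mm: float = 0.3
    median_kernel: int = 3
    frangi_scales: Tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    frangi_alpha: float = 0.5
    frangi_beta: float = 0.5
    frangi_c: Optional[float] = None  # None = auto

    def __post_init__(self) -> None:
        self.frangi_scales = tuple(float(s) for s in self.frangi_scales)

    def frangi(self) -> FrangiConfig:
        return FrangiConfig(
            scales=tuple(self.frangi_scales),
            alpha=self.frangi_alpha,
            beta=self.frangi_beta,
            c=self.frangi_c,
        )


@dataclass
class SegmentationConfig:
    window_frac: float = 1.0 / 8.0
    sensitivity: float = 0.15
    min_object_vox: int = 27
    slice_axis: int = 0  # 0 = en-face slices
    min_intensity_frac: float = 0.05  # absolute floor as fraction of volume max


@dataclass
class SkeletonConfig:
    prune_spur_vox: int = 5


@dataclass
class MetricsConfig:
    smooth_window: int = 3
    angle_floor: float = 1e-6
    min_branch_points: int = 4


@dataclass
class HeatmapConfig:
    roi_size_mm: Tuple[float, float] = (2.5, 2.5)  # en-face (y, x); depth = window
    overlap_frac: float = 0.3

    def __post_init__(self) -> None:
        self.roi_size_mm = tuple(float(s) for s in self.roi_size_mm)


@dataclass
class DetectionConfig:
    vd_std_lim: float = 4e-5
    sbcc_thr_frac: float = 0.75
    nbcc_init_frac: float = 0.20
    nbcc_step_frac: float = 0.30
    disk_radius_px: int = 20
    min_component_px: int = 10
    roi_size_mm: Tuple[float, float, float] = (0.3, 2.5, 2.5)  # (z, y, x)
    literal_global_max: bool = False  # centre lesion ROI on the global VD max

    def __post_init__(self) -> None:
        self.roi_size_mm = tuple(float(s) for s in self.roi_size_mm)
        for name in ("sbcc_thr_frac", "nbcc_init_frac", "nbcc_step_frac"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.disk_radius_px < 1:
            raise ValueError("disk_radius_px must be >= 1")


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    skeleton: SkeletonConfig = field(default_factory=SkeletonConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    heatmap: HeatmapConfig = field(default_factory=HeatmapConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        sub = {
            "preprocess": PreprocessConfig,
            "segmentation": SegmentationConfig,
            "skeleton": SkeletonConfig,
            "metrics": MetricsConfig,
            "heatmap": HeatmapConfig,
            "detection": DetectionConfig,
        }
        kwargs = {}
        for name, subcls in sub.items():
            if name in d:
                kwargs[name] = _from_dict(subcls, d.pop(name))
        if "seed" in d:
            kwargs["seed"] = int(d.pop("seed"))
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def save(self, path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=1))
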