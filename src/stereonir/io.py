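"""Image and table I/O plus pipeline configuration.

Images travel as single-channel TIFF (8/16-bit integer or 32-bit float);
depth and disparity maps are 32-bit float TIFF with NaN marking invalid
pixels; colour renders are 8-bit PNG; per-vessel tables are CSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .enhance import EnhancementParams
from .geometry import CameraModel, StereoRig
from .phantom import MediumModel, medium_for_band
from .sgm import SGMParams

_ALLOWED_DTYPES = ("uint8", "uint16", "float32")


class ImageFormatError(ValueError):
    pass


def read_image(path) -> np.ndarray:
    """Read a single-channel TIFF; refuses multi-channel or exotic dtypes."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ImageFormatError(
            f"{path}: expected a single-channel 2D image, got shape {arr.shape}; "
            "convert RGB/stacked input to grayscale first"
        )
    if arr.dtype == np.float64:
        arr = arr.astype(np.float32)
    if arr.dtype.name not in _ALLOWED_DTYPES:
        raise ImageFormatError(
            f"{path}: unsupported dtype {arr.dtype}; use uint8, uint16 or float32"
        )
    return arr


def write_image(path, image: np.ndarray) -> None:
    """Write a single-channel TIFF losslessly (float maps keep NaN)."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ImageFormatError("only single-channel 2D images are written")
    if img.dtype in (np.float64, np.float16):
        img = img.astype(np.float32)
    if img.dtype.name not in _ALLOWED_DTYPES:
        raise ImageFormatError(f"unsupported dtype {img.dtype}")
    tifffile.imwrite(str(path), img)


def write_png(path, rgb: np.ndarray) -> None:
    iio.imwrite(str(path), np.asarray(rgb, dtype=np.uint8))


@dataclass
class PipelineConfig:
    """Fully resolved configuration of one pipeline run."""

    focal_length_mm: float = 35.0
    pixel_pitch_um: float = 20.0
    sensor_width: int = 640
    sensor_height: int = 512
    baseline_mm: float = 40.0
    object_distance_mm: float = 450.0
    reference_plane_offset_mm: float = 0.0
    z_span_mm: float = 15.0
    enhancement: EnhancementParams = field(default_factory=EnhancementParams)
    sgm: SGMParams | None = None  # None: derive the search range from geometry
    band: str = "LP1300"
    medium_overrides: dict = field(default_factory=dict)
    display_range: tuple[float, float] = (-6.0, -10.0)
    min_component_size: int = 50
    threshold: str | float = "adaptive"
    seed: int = 0

    def rig(self) -> StereoRig:
        cam = CameraModel(
            focal_length=self.focal_length_mm,
            pixel_pitch=self.pixel_pitch_um,
            sensor_width=self.sensor_width,
            sensor_height=self.sensor_height,
        )
        return StereoRig(
            camera=cam,
            baseline=self.baseline_mm,
            reference_distance=self.object_distance_mm,
            reference_plane_offset=self.reference_plane_offset_mm,
        )

    def sgm_params(self) -> SGMParams:
        if self.sgm is not None:
            return self.sgm
        d_min, d_max = self.rig().disparity_search_range(self.z_span_mm)
        return SGMParams(d_min=d_min, d_max=d_max)

    def medium(self) -> MediumModel:
        return medium_for_band(self.band, **self.medium_overrides)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["enhancement"]["scales"] = list(d["enhancement"]["scales"])
        d["display_range"] = list(d["display_range"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


_TOP_KEYS = {f for f in PipelineConfig.__dataclass_fields__}


def load_config(path_or_dict) -> PipelineConfig:
    """Load a YAML/JSON config; unknown or malformed keys are errors."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "enhancement" in kwargs and isinstance(kwargs["enhancement"], dict):
        e = dict(kwargs["enhancement"])
        if "scales" in e:
            e["scales"] = tuple(float(s) for s in e["scales"])
        bad = set(e) - set(EnhancementParams.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown enhancement keys: {sorted(bad)}")
        kwargs["enhancement"] = EnhancementParams(**e)
    if "sgm" in kwargs and isinstance(kwargs["sgm"], dict):
        bad = set(kwargs["sgm"]) - set(SGMParams.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown sgm keys: {sorted(bad)}")
        kwargs["sgm"] = SGMParams(**kwargs["sgm"])
    if "display_range" in kwargs:
        dr = kwargs["display_range"]
        if len(dr) != 2:
            raise ValueError("display_range must have two entries")
        kwargs["display_range"] = (float(dr[0]), float(dr[1]))
    try:
        return PipelineConfig(**kwargs)
    except TypeError as exc:  # missing/duplicate field
        raise ValueError(f"invalid config: {exc}") from exc


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
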