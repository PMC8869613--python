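"""Stereo triangulation for a translating-camera NIR-II rig.

A single camera on a one-dimensional stage acquires a left-eye and a
right-eye view separated by a baseline ``b``.  For an object at distance
``Z`` (much larger than the focal length ``f``) the horizontal disparity
``d = X_L - X_R`` measured in metric sensor units obeys the similar-triangle
relation ``Z = b * f / d``, and the theoretical depth resolution for a
disparity error ``dp`` is ``D_r = Z**2 * dp / (f * b)``.

Depths are reported as signed millimetres relative to a configurable
reference plane, negative meaning deeper (farther from the camera), which is
the display convention used for vascular depth maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidDisparityError(ValueError):
    """Raised when a disparity admits no triangulation (d <= 0)."""


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera with a square-pixel sensor.

    Parameters
    ----------
    focal_length : float
        Lens focal length in mm.
    pixel_pitch : float
        Pixel pitch in micrometres per pixel.  Not a property of the lens:
        it converts pixel disparities to the metric disparities triangulation
        needs.  Default 20 um, typical for 640x512 InGaAs sensors.
    sensor_width, sensor_height : int
        Sensor size in pixels.
    principal_point : tuple of float, optional
        (x, y) pixel coordinates of the optical axis; defaults to the sensor
        centre.
    """

    focal_length: float = 35.0
    pixel_pitch: float = 20.0
    sensor_width: int = 640
    sensor_height: int = 512
    principal_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.focal_length <= 0:
            raise ValueError("focal_length must be > 0")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.sensor_width <= 0 or self.sensor_height <= 0:
            raise ValueError("sensor dimensions must be > 0")
        cx, cy = self.center
        if not (0 <= cx <= self.sensor_width and 0 <= cy <= self.sensor_height):
            raise ValueError("principal_point must lie inside the sensor")

    @property
    def center(self) -> tuple[float, float]:
        if self.principal_point is not None:
            return self.principal_point
        return (self.sensor_width / 2.0, self.sensor_height / 2.0)

    @property
    def pixel_pitch_mm(self) -> float:
        return self.pixel_pitch * 1e-3

    def object_pixel_size(self, distance: float) -> float:
        """Object-space size of one pixel (mm) at the given distance."""
        return self.pixel_pitch_mm * distance / self.focal_length


@dataclass(frozen=True)
class StereoRig:
    """Camera plus baseline geometry.

    ``reference_distance`` is the camera-to-reference-plane distance Z0 in mm
    (450 mm for the system modelled here); ``baseline`` is the stage travel b
    in mm (40 mm).  ``reference_plane_offset`` shifts the zero of the reported
    depth scale relative to Z0 (mm; default 0, i.e. depth 0 at Z = Z0).
    """

    camera: CameraModel = field(default_factory=CameraModel)
    baseline: float = 40.0
    reference_distance: float = 450.0
    reference_plane_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be > 0")
        if self.reference_distance <= 0:
            raise ValueError("reference_distance must be > 0")
        if self.reference_distance <= 10 * self.camera.focal_length:
            raise ValueError(
                "reference_distance must be much larger than the focal length"
            )

    @property
    def reference_disparity_px(self) -> float:
        """Disparity (pixels) of a point on the reference plane."""
        d_mm = self.baseline * self.camera.focal_length / self.reference_distance
        return d_mm / self.camera.pixel_pitch_mm

    def disparity_search_range(
        self, z_span: float = 15.0, pad: int = 2
    ) -> tuple[int, int]:
        """Integer disparity bounds (px) covering Z0 +- z_span mm, padded."""
        bf = self.baseline * self.camera.focal_length
        pitch = self.camera.pixel_pitch_mm
        d_lo = bf / (self.reference_distance + z_span) / pitch
        d_hi = bf / (self.reference_distance - z_span) / pitch
        return int(np.floor(d_lo)) - pad, int(np.ceil(d_hi)) + pad


@dataclass
class DisparityMap:
    """Per-pixel signed horizontal disparity in pixels with validity mask."""

    values: np.ndarray
    valid: np.ndarray
    search_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share a shape")


@dataclass
class DepthMap:
    """Signed metric depth in mm relative to a reference plane.

    Negative values are deeper than the reference plane.  Invalid pixels are
    NaN in ``values`` and False in ``valid``.
    """

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share a shape")


def disparity_to_distance(disparity_metric, rig: StereoRig):
    """Distance Z = b*f/d from a metric disparity d (mm on the sensor).

    Accepts scalars or arrays.  Raises :class:`InvalidDisparityError` for
    scalar d <= 0 (no triangulation possible).
    """
    d = np.asarray(disparity_metric, dtype=np.float64)
    if d.ndim == 0:
        if d <= 0:
            raise InvalidDisparityError(
                f"disparity must be > 0 for triangulation, got {float(d)}"
            )
        return float(rig.baseline * rig.camera.focal_length / d)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = rig.baseline * rig.camera.focal_length / d
    z[d <= 0] = np.nan
    return z


def distance_to_disparity(distance, rig: StereoRig):
    """Metric disparity d = b*f/Z (mm on the sensor); inverse of the above."""
    z = np.asarray(distance, dtype=np.float64)
    if z.ndim == 0 and z <= 0:
        raise ValueError("distance must be > 0")
    d = rig.baseline * rig.camera.focal_length / z
    return float(d) if np.ndim(distance) == 0 else d


def pixels_to_metric_disparity(disparity_px, camera: CameraModel):
    """Convert a pixel disparity to metric sensor units (mm)."""
    return np.asarray(disparity_px, dtype=np.float64) * camera.pixel_pitch_mm


def metric_to_pixel_disparity(disparity_mm, camera: CameraModel):
    return np.asarray(disparity_mm, dtype=np.float64) / camera.pixel_pitch_mm


def disparity_map_to_depth_map(dmap: DisparityMap, rig: StereoRig) -> DepthMap:
    """Convert a pixel disparity map to signed depth relative to the rig's
    reference plane.

    depth = Z0 + offset - Z, so a point on the reference plane maps to
    ``reference_plane_offset`` and deeper points (smaller disparity, larger Z)
    map to more negative values.  Pixels with invalid or non-positive
    disparity become NaN/invalid.
    """
    if not np.any(dmap.valid):
        raise ValueError("disparity map has an empty valid mask")
    d_mm = pixels_to_metric_disparity(dmap.values, rig.camera)
    valid = dmap.valid & (d_mm > 0)
    z = np.full(d_mm.shape, np.nan)
    z[valid] = rig.baseline * rig.camera.focal_length / d_mm[valid]
    depth = rig.reference_distance + rig.reference_plane_offset - z
    depth[~valid] = np.nan
    return DepthMap(values=depth, valid=valid)


def theoretical_depth_resolution(rig: StereoRig, disparity_error: float) -> float:
    """Depth resolution D_r = Z**2 * dp / (f * b) for disparity error dp (mm).

    dp = 0 is allowed and gives D_r = 0; negative arguments are a domain
    error.
    """
    if disparity_error < 0:
        raise ValueError("disparity_error must be >= 0")
    z = rig.reference_distance
    return z * z * disparity_error / (rig.camera.focal_length * rig.baseline)


def disparity_error_for_resolution(rig: StereoRig, depth_resolution: float) -> float:
    """Invert the depth-resolution relation: dp = D_r * f * b / Z**2 (mm)."""
    if depth_resolution < 0:
        raise ValueError("depth_resolution must be >= 0")
    z = rig.reference_distance
    return depth_resolution * rig.camera.focal_length * rig.baseline / (z * z)
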