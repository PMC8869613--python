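"""Synthetic tube-phantom renderer with a scattering-medium model.

Replaces the physical apparatus: 3D tube scenes (glass capillaries or
printed vessel phantoms filled with a NIR-II fluorophore) are projected
through the stereo rig's pinhole optics into left/right sensor images, and a
depth-dependent attenuation + point-spread model emulates imaging through a
1% Intralipid tissue phantom in the 1100-LP / 1300-LP / 1400-LP collection
bands.

A tube's transverse emission profile is the chord length of its cylinder
bore (peak-normalised ``sqrt(1 - (s/r)**2)``), not a Gaussian; the Gaussian
enters only through the medium PSF.  Attenuation and PSF growth are
calibrated so the rendered capillary series reproduces the measured
half-intensity depths (4 mm in 1100-LP, 2 mm in 1300-LP) and the measured
capillary FWHM at 1 and 6 mm depth (1.87/9.08 mm in 1100-LP, 1.25/2.44 mm in
1300-LP); see scripts/calibrate_medium.py for the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import StereoRig

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

# Glass capillary used in the depth-series study: OD 1.5 mm / ID 1.1 mm;
# the fluorophore fills the bore, so the emitting radius is 0.55 mm.
CAPILLARY_INNER_RADIUS_MM = 0.55


@dataclass(frozen=True)
class Tube:
    """A cylindrical emitter.

    centerline: (N, 3) polyline in mm — lateral x, vertical y, and depth z
    below the reference plane (positive = deeper / farther from the camera).
    """

    centerline: np.ndarray
    radius: float
    emission: float = 1.0

    def __post_init__(self) -> None:
        cl = np.atleast_2d(np.asarray(self.centerline, dtype=np.float64))
        if cl.ndim != 2 or cl.shape[1] != 3 or cl.shape[0] < 2:
            raise ValueError("centerline must be an (N>=2, 3) polyline")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.emission < 0:
            raise ValueError("emission must be >= 0")
        object.__setattr__(self, "centerline", cl)

    @property
    def depth(self) -> float:
        """Mean depth of the centerline below the reference plane (mm)."""
        return float(self.centerline[:, 2].mean())


@dataclass(frozen=True)
class VesselScene:
    """A set of tubes in a lateral field, immersed in a scattering medium.

    surface_offset is the depth of the medium surface relative to the
    reference plane (mm); the optical path of a tube at depth z is
    z - surface_offset.
    """

    tubes: tuple[Tube, ...]
    extent: tuple[float, float] = (40.0, 30.0)
    surface_offset: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tubes", tuple(self.tubes))


@dataclass(frozen=True)
class MediumModel:
    """Band-dependent attenuation and PSF growth of the scattering medium.

    mu_eff: effective attenuation coefficient (1/mm); intensity at optical
    depth z scales as exp(-mu_eff * (z - 1)) relative to 1 mm.
    psf_fwhm_at_1mm / psf_fwhm_slope: Gaussian PSF FWHM (mm) at 1 mm depth
    and its growth per mm of depth.
    """

    band: str = "LP1300"
    mu_eff: float = np.log(2.0)
    psf_fwhm_at_1mm: float = 0.8
    psf_fwhm_slope: float = 0.3

    def __post_init__(self) -> None:
        if self.mu_eff < 0:
            raise ValueError("mu_eff must be >= 0")
        if self.psf_fwhm_at_1mm < 0 or self.psf_fwhm_slope < 0:
            raise ValueError("PSF parameters must be >= 0")

    def psf_fwhm(self, depth_mm: float) -> float:
        return max(self.psf_fwhm_at_1mm + self.psf_fwhm_slope * (depth_mm - 1.0), 0.0)

    def attenuation(self, depth_mm: float) -> float:
        return float(np.exp(-self.mu_eff * (depth_mm - 1.0)))


# Shipped defaults.  mu_eff comes directly from the measured half-intensity
# depths (halved at 4 mm in 1100-LP -> ln2/3; at 2 mm in 1300-LP -> ln2).
# PSF numbers come from scripts/calibrate_medium.py, which inverts the
# render -> profile -> Gaussian-fit pipeline against the measured capillary
# FWHM at 1 and 6 mm depth.  LP1400 has no measured series; its values are a
# qualitative extrapolation (sharper PSF, faster water-absorption decay).
_BAND_DEFAULTS: dict[str, dict[str, float]] = {
    "LP1100": {"mu_eff": np.log(2.0) / 3.0, "psf_fwhm_at_1mm": 1.7608, "psf_fwhm_slope": 1.4595},
    "LP1300": {"mu_eff": np.log(2.0), "psf_fwhm_at_1mm": 1.0714, "psf_fwhm_slope": 0.2574},
    "LP1400": {"mu_eff": 1.0, "psf_fwhm_at_1mm": 0.86, "psf_fwhm_slope": 0.21},
}


def medium_for_band(band: str, **overrides) -> MediumModel:
    """Shipped MediumModel defaults for a collection band."""
    if band not in _BAND_DEFAULTS:
        raise ValueError(f"unknown band {band!r}; choose from {sorted(_BAND_DEFAULTS)}")
    m = MediumModel(band=band, **_BAND_DEFAULTS[band])
    return replace(m, **overrides) if overrides else m


@dataclass(frozen=True)
class NoiseModel:
    """Shot-plus-read-noise model of the InGaAs detector.

    photon_scale: detected photons per digital count; shot-noise variance of
    a pixel with mean I counts is I / photon_scale.  read_noise_sd: additive
    Gaussian read noise in counts.  Output is reproducible for a fixed seed.
    """

    photon_scale: float = 0.25
    read_noise_sd: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


def _rig_for_shape(rig: StereoRig, shape: tuple[int, int] | None) -> StereoRig:
    """Rig whose sensor matches a custom render frame (principal point at the
    frame centre); the optics are unchanged."""
    if shape is None:
        return rig
    H, W = shape
    cam = rig.camera
    if (cam.sensor_height, cam.sensor_width) == (H, W):
        return rig
    from dataclasses import replace as _replace

    cam2 = _replace(cam, sensor_width=W, sensor_height=H, principal_point=None)
    return _replace(rig, camera=cam2)


def _project_points(points: np.ndarray, rig: StereoRig, view: str) -> np.ndarray:
    """Project (N, 3) scene points (mm) to continuous pixel coordinates."""
    if view not in ("left", "right"):
        raise ValueError("view must be 'left' or 'right'")
    cam = rig.camera
    cam_x = -rig.baseline / 2.0 if view == "left" else rig.baseline / 2.0
    cx, cy = cam.center
    Z = rig.reference_distance + points[:, 2]
    u = cx + cam.focal_length * (points[:, 0] - cam_x) / Z / cam.pixel_pitch_mm
    v = cy + cam.focal_length * points[:, 1] / Z / cam.pixel_pitch_mm
    return np.column_stack([u, v, Z])


def _segment_distance(px: np.ndarray, py: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Distance from grid points to segment a->b (all in pixel units)."""
    ab = b[:2] - a[:2]
    denom = float(ab @ ab)
    if denom == 0:
        t = np.zeros_like(px)
    else:
        t = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom
        t = np.clip(t, 0.0, 1.0)
    dx = px - (a[0] + t * ab[0])
    dy = py - (a[1] + t * ab[1])
    return np.hypot(dx, dy)


def project_tube(tube: Tube, rig: StereoRig, view: str, shape: tuple[int, int] | None = None):
    """Ideal (pre-medium) image of one tube through a pinhole camera.

    Returns the emission image: the peak-normalised chord-length profile of
    the cylinder bore around the projected centerline, scaled by the tube's
    emission.
    """
    cam = rig.camera
    H, W = shape if shape is not None else (cam.sensor_height, cam.sensor_width)
    pts = _project_points(tube.centerline, rig, view)
    img = np.zeros((H, W), dtype=np.float64)
    if pts[:, 0].max() < 0 or pts[:, 0].min() > W or pts[:, 1].max() < 0 or pts[:, 1].min() > H:
        warnings.warn("tube projects outside the field of view; excluded", stacklevel=2)
        return img
    for a, b in zip(pts[:-1], pts[1:]):
        z_seg = 0.5 * (a[2] + b[2])
        mmpp = cam.object_pixel_size(z_seg)  # mm per pixel at this depth
        r_px = tube.radius / mmpp
        lo_c = max(int(np.floor(min(a[0], b[0]) - r_px - 1)), 0)
        hi_c = min(int(np.ceil(max(a[0], b[0]) + r_px + 2)), W)
        lo_r = max(int(np.floor(min(a[1], b[1]) - r_px - 1)), 0)
        hi_r = min(int(np.ceil(max(a[1], b[1]) + r_px + 2)), H)
        if lo_c >= hi_c or lo_r >= hi_r:
            continue
        py, px = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        dist_mm = _segment_distance(px.astype(float), py.astype(float), a, b) * mmpp
        inside = dist_mm < tube.radius
        prof = np.zeros_like(dist_mm)
        prof[inside] = np.sqrt(1.0 - (dist_mm[inside] / tube.radius) ** 2)
        np.maximum(img[lo_r:hi_r, lo_c:hi_c], tube.emission * prof, out=img[lo_r:hi_r, lo_c:hi_c])
    return img


def project_scene(
    scene: VesselScene, rig: StereoRig, view: str, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Ideal emission image of the whole scene (no medium, no noise)."""
    imgs = [project_tube(t, rig, view, shape) for t in scene.tubes]
    return np.sum(imgs, axis=0) if imgs else np.zeros(shape or (rig.camera.sensor_height, rig.camera.sensor_width))


def apply_medium(image, depths, medium: MediumModel, pixel_size_mm: float = 0.1):
    """Attenuate and blur per-depth emission images.

    Accepts either a single 2D image with a scalar optical depth, or a
    sequence of per-tube images with matching depths (summed after each is
    attenuated by exp(-mu_eff (z - 1)) and blurred with the depth's Gaussian
    PSF).  pixel_size_mm converts the PSF FWHM to pixels.
    """
    single = isinstance(depths, (int, float))
    images = [np.asarray(image, dtype=np.float64)] if single else [np.asarray(a, float) for a in image]
    zs = [float(depths)] if single else [float(z) for z in depths]
    if len(images) != len(zs):
        raise ValueError("need one depth per image")
    out = np.zeros(images[0].shape, dtype=np.float64)
    for img, z in zip(images, zs):
        sigma_px = medium.psf_fwhm(z) / FWHM_PER_SIGMA / pixel_size_mm
        layer = img * medium.attenuation(z)
        if sigma_px > 0:
            layer = gaussian_filter(layer, sigma_px, mode="nearest")
        out += layer
    return out


def add_noise(image: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Shot + read noise, clipped and quantised to a 16-bit image.

    Shot noise: Poisson with mean image*photon_scale, rescaled to counts, so
    the variance of a flat field is mean/photon_scale + read_noise_sd**2.
    """
    img = np.clip(np.asarray(image, dtype=np.float64), 0.0, None)
    rng = np.random.default_rng(noise.seed)
    counts = rng.poisson(img * noise.photon_scale) / noise.photon_scale
    if noise.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, noise.read_noise_sd, size=img.shape)
    return np.clip(np.round(counts), 0, 65535).astype(np.uint16)


def render_truth(
    scene: VesselScene, rig: StereoRig, shape: tuple[int, int] | None = None
):
    """Ground-truth depth, mask and per-tube labels in the left view.

    Depth follows the signed display convention (reference_plane_offset - z,
    negative = deeper); where tubes overlap the shallower tube wins.
    """
    rig = _rig_for_shape(rig, shape)
    cam = rig.camera
    H, W = shape if shape is not None else (cam.sensor_height, cam.sensor_width)
    depth = np.full((H, W), np.nan)
    labels = np.zeros((H, W), dtype=np.int32)
    z_at = np.full((H, W), np.inf)
    for i, tube in enumerate(scene.tubes):
        footprint = project_tube(Tube(tube.centerline, tube.radius, 1.0), rig, "left", (H, W)) > 0
        take = footprint & (tube.depth < z_at)
        z_at[take] = tube.depth
        depth[take] = rig.reference_plane_offset - tube.depth
        labels[take] = i + 1
    mask = labels > 0
    return depth, mask, labels


def render_stereo_pair(
    scene: VesselScene,
    rig: StereoRig,
    medium: MediumModel,
    noise: NoiseModel | None = None,
    shape: tuple[int, int] | None = None,
    dn_per_emission: float | None = None,
    peak_dn: float = 30000.0,
):
    """Render (left, right) images plus ground truth for scoring.

    Each tube is projected, attenuated and blurred at its own optical depth,
    then the views are scaled to detector counts and noise is added.  By
    default the exposure is set the way a bench operator would: the
    brightest structure reaches peak_dn counts (well inside the 16-bit
    range); pass dn_per_emission to fix an absolute scale instead.  Returns
    (left, right, truth) with truth = dict(depth=..., mask=..., labels=...).
    """
    rig = _rig_for_shape(rig, shape)
    cam = rig.camera
    H, W = shape if shape is not None else (cam.sensor_height, cam.sensor_width)
    views = []
    gain = dn_per_emission
    for iv, view in enumerate(("left", "right")):
        img = np.zeros((H, W))
        for tube in scene.tubes:
            layer = project_tube(tube, rig, view, (H, W))
            z = max(tube.depth - scene.surface_offset, 0.0)
            mmpp = cam.object_pixel_size(rig.reference_distance + tube.depth)
            img += apply_medium(layer, z, medium, pixel_size_mm=mmpp)
        if gain is None:  # auto-exposure from the left view
            gain = peak_dn / img.max() if img.max() > 0 else 1.0
        img *= gain
        if noise is not None:
            img = add_noise(img, replace(noise, seed=noise.seed * 2 + iv))
        views.append(img)
    depth, mask, labels = render_truth(scene, rig, (H, W))
    truth = {"depth": depth, "mask": mask, "labels": labels}
    return views[0], views[1], truth


def make_two_layer_phantom(
    upper_depth: float = 7.5,
    lower_depth: float = 8.5,
    diameter: float = 1.0,
    extent: tuple[float, float] = (40.0, 30.0),
    surface_offset: float = 3.5,
) -> VesselScene:
    """Canonical two-layer abdominal-vessel phantom.

    Four 1 mm-diameter tubes in a 40 x 30 mm lateral field: two at 7.5 mm
    depth below the reference plane (the phantom top) and two at 8.5 mm, in
    a gently branching layout; the 1 mm layer gap is the depth-separation
    test case for the stereo system.  The default surface_offset places the
    scattering-medium surface 3.5 mm above the upper layer so the optical
    imaging depth of the layers is 4 and 5 mm, matching the phantom's
    stated ~5 mm imaging depth.
    """
    r = diameter / 2.0
    hy = extent[1] / 2.0 - 2.0

    def line(x0, x1, z):
        ys = np.linspace(-hy, hy, 5)
        xs = np.linspace(x0, x1, 5)
        return np.column_stack([xs, ys, np.full(5, z)])

    tubes = (
        Tube(line(-13.0, -10.0, upper_depth), r),
        Tube(line(-5.0, -7.0, lower_depth), r),
        Tube(line(3.0, 5.5, upper_depth), r),
        Tube(line(11.0, 13.5, lower_depth), r),
    )
    return VesselScene(tubes=tubes, extent=extent, surface_offset=surface_offset)


def make_tube_pair_scene(
    depth_gap: float,
    base_depth: float = 7.5,
    diameter: float = 1.0,
    extent: tuple[float, float] = (24.0, 18.0),
) -> VesselScene:
    """Two parallel tubes separated in depth by depth_gap (mm).

    Compact scene used to probe the empirical depth resolution of the
    pipeline at a given stereo geometry.
    """
    r = diameter / 2.0
    hy = extent[1] / 2.0 - 1.5

    def line(x, z):
        ys = np.linspace(-hy, hy, 3)
        return np.column_stack([np.full(3, x), ys, np.full(3, z)])

    tubes = (
        Tube(line(-5.0, base_depth), r),
        Tube(line(5.0, base_depth + depth_gap), r),
    )
    return VesselScene(tubes=tubes, extent=extent, surface_offset=3.5)


def render_capillary(
    depth_mm: float,
    medium: MediumModel,
    pixel_size_mm: float = 0.1,
    shape: tuple[int, int] = (480, 64),
    radius_mm: float = CAPILLARY_INNER_RADIUS_MM,
    emission: float = 1.0,
) -> np.ndarray:
    """One noise-free image of a horizontal capillary at an optical depth.

    Rendered on a plain metric grid (fixed magnification) — the depth-series
    bench images the capillary from above, so stereo projection is not
    involved; only the medium model acts.
    """
    H, W = shape
    y = (np.arange(H) - H / 2.0 + 0.5) * pixel_size_mm
    prof = np.zeros(H)
    inside = np.abs(y) < radius_mm
    prof[inside] = np.sqrt(1.0 - (y[inside] / radius_mm) ** 2)
    ideal = emission * np.repeat(prof[:, None], W, axis=1)
    sigma_px = medium.psf_fwhm(depth_mm) / FWHM_PER_SIGMA / pixel_size_mm
    img = ideal * medium.attenuation(depth_mm)
    if sigma_px > 0:
        img = gaussian_filter(img, sigma_px, mode=("constant", "nearest"))
    return img


def capillary_footprint(
    pixel_size_mm: float = 0.1,
    shape: tuple[int, int] = (480, 64),
    radius_mm: float = CAPILLARY_INNER_RADIUS_MM,
) -> np.ndarray:
    """Boolean footprint of the capillary bore on the metric grid."""
    H, W = shape
    y = (np.arange(H) - H / 2.0 + 0.5) * pixel_size_mm
    return np.repeat((np.abs(y) < radius_mm)[:, None], W, axis=1)


def make_capillary_depth_series(
    depths,
    medium: MediumModel,
    pixel_size_mm: float = 0.1,
    shape: tuple[int, int] = (480, 64),
) -> list[np.ndarray]:
    """Noise-free capillary images at each immersion depth (mm)."""
    depths = [float(z) for z in depths]
    if any(z <= 0 for z in depths):
        raise ValueError("depths must be positive")
    return [render_capillary(z, medium, pixel_size_mm, shape) for z in depths]
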