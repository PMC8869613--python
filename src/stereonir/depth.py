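"""Disparity-to-depth conversion on vessel masks and depth colouring.

Depth maps are displayed on the red-yellow-green-blue sequence used for
vascular depth encoding: red at the shallow end of the display range,
through yellow and green, to blue at the deep end; invalid pixels are black.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .enhance import VesselMask
from .geometry import DepthMap, DisparityMap, StereoRig, disparity_map_to_depth_map

# equally spaced anchors of the depth colour path
_ANCHORS = np.array(
    [[255, 0, 0], [255, 255, 0], [0, 255, 0], [0, 0, 255]], dtype=np.float64
)


def reconstruct_depth(dmap: DisparityMap, rig: StereoRig, mask: VesselMask | np.ndarray) -> DepthMap:
    """Metric depth restricted to valid disparity pixels inside the vessel
    mask; everything else is NaN/invalid."""
    m = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask, dtype=bool)
    if m.shape != dmap.values.shape:
        raise ValueError("mask and disparity shapes disagree")
    depth = disparity_map_to_depth_map(dmap, rig)
    keep = depth.valid & m
    if not keep.any():
        warnings.warn("no valid masked depth pixels", stacklevel=2)
    values = np.where(keep, depth.values, np.nan)
    return DepthMap(values=values, valid=keep)


def per_vessel_depth(depth: DepthMap, labels: np.ndarray, statistic: str = "mean") -> pd.DataFrame:
    """Per-component depth statistics.

    labels: integer image of connected vessel components (0 = background).
    Returns a DataFrame with columns component, mean_depth_mm, std_mm,
    n_pixels; components with no valid pixels get NaN and count 0.
    """
    labels = np.asarray(labels)
    rows = []
    for lab in np.unique(labels[labels > 0]):
        sel = (labels == lab) & depth.valid
        vals = depth.values[sel]
        if vals.size == 0:
            rows.append((int(lab), np.nan, np.nan, 0))
        else:
            center = np.median(vals) if statistic == "median" else vals.mean()
            rows.append((int(lab), float(center), float(vals.std()), int(vals.size)))
    return pd.DataFrame(rows, columns=["component", "mean_depth_mm", "std_mm", "n_pixels"])


def colorize_depth(depth: DepthMap, display_range: tuple[float, float]) -> np.ndarray:
    """Render a depth map as an 8-bit RGB image.

    display_range = (shallow, deep) in mm: the shallow end maps to red and
    the deep end to blue via piecewise-linear interpolation through
    red-yellow-green-blue; out-of-range depths clamp to the end colours and
    invalid pixels are black.
    """
    lo, hi = display_range
    if lo == hi:
        raise ValueError("display_range must span a nonzero interval")
    t = (depth.values - lo) / (hi - lo)
    t = np.clip(np.nan_to_num(t, nan=0.0), 0.0, 1.0)
    n_seg = len(_ANCHORS) - 1
    pos = t * n_seg
    idx = np.minimum(pos.astype(int), n_seg - 1)
    frac = pos - idx
    rgb = (1.0 - frac[..., None]) * _ANCHORS[idx] + frac[..., None] * _ANCHORS[idx + 1]
    rgb[~depth.valid] = 0.0
    return np.round(rgb).astype(np.uint8)
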