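"""Profile quantification: Gaussian FWHM fits, intensity-vs-depth curves,
and depth-recovery scoring against renderer ground truth.

The spatial-resolution metric used throughout is the full width at half
maximum (FWHM) of a Gaussian least-squares fit to a line profile across a
vessel or capillary, FWHM = 2 sqrt(2 ln 2) sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit

from .geometry import DepthMap

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class ProfileFit:
    """Result of a Gaussian fit a*exp(-(x-mu)**2/(2 s**2)) + b."""

    amplitude: float
    center: float
    sigma: float
    offset: float
    rmse: float
    converged: bool = True

    @property
    def fwhm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma


def line_profile(image, start, end, width: int = 1, spacing: float = 1.0):
    """Intensity profile along a segment, averaged across `width`
    perpendicular samples.

    start/end are (row, col) pixel points; spacing attaches a physical step
    (e.g. mm per pixel) to the returned sample positions.  Returns
    (positions, values).
    """
    img = np.asarray(image, dtype=np.float64)
    start = np.asarray(start, dtype=np.float64)
    end = np.asarray(end, dtype=np.float64)
    length = float(np.hypot(*(end - start)))
    if length == 0:
        raise ValueError("degenerate zero-length profile segment")
    for p in (start, end):
        if not (0 <= p[0] <= img.shape[0] - 1 and 0 <= p[1] <= img.shape[1] - 1):
            raise ValueError("profile endpoints must lie inside the image")
    n = int(np.ceil(length)) + 1
    t = np.linspace(0.0, 1.0, n)
    line = start[None, :] + t[:, None] * (end - start)[None, :]
    direction = (end - start) / length
    normal = np.array([-direction[1], direction[0]])
    offsets = np.arange(width, dtype=np.float64) - (width - 1) / 2.0
    prof = np.zeros(n)
    for o in offsets:
        pts = line + o * normal[None, :]
        prof += map_coordinates(img, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")
    prof /= len(offsets)
    positions = t * length * spacing
    return positions, prof


def fit_gaussian_fwhm(profile, positions=None) -> ProfileFit:
    """Least-squares Gaussian fit of a 1D profile.

    Initialisation: amplitude = max - min, center = argmax, sigma from the
    second moment of the baseline-subtracted profile, offset = min; bounded
    so sigma stays positive.  A non-convergent fit returns a flagged result
    (converged=False) carrying the initial estimates rather than a silent
    number.
    """
    y = np.asarray(profile, dtype=np.float64)
    x = np.arange(y.size, dtype=np.float64) if positions is None else np.asarray(positions, float)
    if y.size < 5:
        raise ValueError("profile needs at least 5 samples")
    rng_y = y.max() - y.min()
    if rng_y <= 0:
        raise ValueError("profile has no dynamic range")
    off0 = float(y.min())
    amp0 = float(rng_y)
    w = np.clip(y - off0, 0.0, None)
    mu0 = float((x * w).sum() / w.sum())
    var0 = float(((x - mu0) ** 2 * w).sum() / w.sum())
    sig0 = float(np.sqrt(max(var0, (x[1] - x[0]) ** 2 / 12.0)))

    def gauss(x, a, mu, s, b):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * s * s)) + b

    span = float(x[-1] - x[0])
    try:
        popt, _ = curve_fit(
            gauss,
            x,
            y,
            p0=(amp0, mu0, sig0, off0),
            bounds=(
                (0.0, x[0] - span, 1e-9, -np.inf),
                (np.inf, x[-1] + span, 10.0 * span + 1.0, np.inf),
            ),
            maxfev=20000,
        )
        resid = gauss(x, *popt) - y
        return ProfileFit(
            amplitude=float(popt[0]),
            center=float(popt[1]),
            sigma=float(popt[2]),
            offset=float(popt[3]),
            rmse=float(np.sqrt(np.mean(resid**2))),
            converged=True,
        )
    except RuntimeError:
        return ProfileFit(amp0, mu0, sig0, off0, rmse=float("nan"), converged=False)


def fit_capillary_fwhm(image, pixel_size_mm: float = 1.0, width: int = 1) -> ProfileFit:
    """Gaussian FWHM (physical units) of a horizontal tube's transverse
    profile, taken down the central column."""
    img = np.asarray(image, dtype=np.float64)
    H, W = img.shape
    col = W // 2
    pos, prof = line_profile(img, (0, col), (H - 1, col), width=width, spacing=pixel_size_mm)
    return fit_gaussian_fwhm(prof, pos)


def intensity_vs_depth(series, roi):
    """Normalised mean-ROI intensity versus depth, plus half-intensity depth.

    series: iterable of (depth_mm, image); roi: boolean mask shared by all
    images.  Intensities are means over the ROI, normalised to the
    shallowest depth; the half-intensity depth is found by piecewise-linear
    interpolation at the first crossing of 0.5 (a warning is emitted if the
    curve is non-monotone or never crosses).

    Returns (depths, normalised intensities, half_depth or None).
    """
    pairs = sorted(((float(z), np.asarray(img, float)) for z, img in series), key=lambda p: p[0])
    if len(pairs) < 2:
        raise ValueError("need at least two depths")
    roi = np.asarray(roi, dtype=bool)
    depths = np.array([z for z, _ in pairs])
    vals = np.array([img[roi].mean() for _, img in pairs])
    norm = vals / vals[0]
    if np.any(np.diff(norm) > 0):
        warnings.warn("intensity-depth curve is non-monotone", stacklevel=2)
    half = None
    for i in range(1, norm.size):
        if norm[i] <= 0.5 <= norm[i - 1]:
            f = (norm[i - 1] - 0.5) / (norm[i - 1] - norm[i])
            half = float(depths[i - 1] + f * (depths[i] - depths[i - 1]))
            break
    if half is None:
        warnings.warn("curve never crosses half intensity", stacklevel=2)
    return depths, norm, half


def depth_recovery_metrics(measured: DepthMap, truth_depth, truth_mask, truth_labels=None):
    """Score a reconstructed depth map against renderer ground truth.

    Returns a dict with per-vessel mean errors (bias, mm), pixelwise RMSE on
    the valid/masked overlap, the estimated layer separation (difference of
    the two depth-cluster means when labels are given), and the valid pixel
    fraction.
    """
    truth_depth = np.asarray(truth_depth, dtype=np.float64)
    truth_mask = np.asarray(truth_mask, dtype=bool)
    overlap = measured.valid & truth_mask & np.isfinite(truth_depth)
    if not overlap.any():
        raise ValueError("no valid overlap between measurement and truth")
    err = measured.values[overlap] - truth_depth[overlap]
    out = {
        "rmse_mm": float(np.sqrt(np.mean(err**2))),
        "bias_mm": float(np.mean(err)),
        "valid_fraction": float(overlap.sum() / truth_mask.sum()),
        "per_vessel": {},
        "separation_mm": None,
        "separation_error_mm": None,
    }
    if truth_labels is not None:
        labels = np.asarray(truth_labels)
        per = {}
        for lab in np.unique(labels[labels > 0]):
            sel = overlap & (labels == lab)
            if sel.sum() == 0:
                per[int(lab)] = {"mean_mm": float("nan"), "bias_mm": float("nan"), "n": 0}
                continue
            per[int(lab)] = {
                "mean_mm": float(measured.values[sel].mean()),
                "truth_mm": float(truth_depth[sel].mean()),
                "bias_mm": float((measured.values[sel] - truth_depth[sel]).mean()),
                "n": int(sel.sum()),
            }
        out["per_vessel"] = per
        truths = sorted({round(v["truth_mm"], 6) for v in per.values() if v["n"] > 0})
        if len(truths) == 2:
            shallow = [v["mean_mm"] for v in per.values() if v["n"] > 0 and round(v["truth_mm"], 6) == truths[1]]
            deep = [v["mean_mm"] for v in per.values() if v["n"] > 0 and round(v["truth_mm"], 6) == truths[0]]
            sep = float(np.mean(shallow) - np.mean(deep))
            out["separation_mm"] = sep
            out["separation_error_mm"] = float(sep - (truths[1] - truths[0]))
    return out
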