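"""Calibrate the scattering-medium PSF defaults against the measured
capillary FWHM values.

The medium model ships image-domain-calibrated defaults: the attenuation
coefficient mu_eff comes directly from the measured half-intensity depths
(4 mm in 1100-LP -> ln2/3 per mm; 2 mm in 1300-LP -> ln2 per mm), and the
PSF parameters are found here by inverting the package's own
render -> transverse profile -> Gaussian fit pipeline so that the fitted
capillary FWHM at 1 mm and 6 mm immersion depth reproduces the measured
values: 1.87 / 9.08 mm (1100-LP) and 1.25 / 2.44 mm (1300-LP).

Run from the repository root:

    python scripts/calibrate_medium.py

and copy the printed numbers into stereonir.phantom._BAND_DEFAULTS.
"""

import numpy as np
from scipy.optimize import brentq

from stereonir.phantom import MediumModel, render_capillary
from stereonir.profiles import fit_capillary_fwhm

PIXEL_MM = 0.1
SHAPE = (480, 64)

# measured capillary FWHM (mm) at immersion depths 1 mm and 6 mm
TARGETS = {
    "LP1100": {"fwhm_1mm": 1.87, "fwhm_6mm": 9.08, "mu_eff": np.log(2) / 3},
    "LP1300": {"fwhm_1mm": 1.25, "fwhm_6mm": 2.44, "mu_eff": np.log(2)},
}


def fitted_fwhm_for_psf(psf_fwhm_mm: float) -> float:
    """Fitted capillary FWHM when the medium PSF has the given FWHM."""
    medium = MediumModel(band="cal", mu_eff=0.0, psf_fwhm_at_1mm=psf_fwhm_mm, psf_fwhm_slope=0.0)
    img = render_capillary(1.0, medium, PIXEL_MM, SHAPE)
    return fit_capillary_fwhm(img, PIXEL_MM).fwhm


def solve_psf(target_fwhm_mm: float) -> float:
    """PSF FWHM whose rendered, fitted capillary FWHM equals the target."""
    return brentq(lambda p: fitted_fwhm_for_psf(p) - target_fwhm_mm, 1e-3, 15.0, xtol=1e-5)


def main() -> None:
    bare = fitted_fwhm_for_psf(1e-3)
    print(f"unblurred capillary chord profile fits to FWHM = {bare:.4f} mm")
    for band, t in TARGETS.items():
        p1 = solve_psf(t["fwhm_1mm"])
        p6 = solve_psf(t["fwhm_6mm"])
        slope = (p6 - p1) / 5.0
        print(
            f'"{band}": {{"mu_eff": {t["mu_eff"]:.6f}, '
            f'"psf_fwhm_at_1mm": {p1:.4f}, "psf_fwhm_slope": {slope:.4f}}},'
        )
        # verify through the shipped model
        m = MediumModel(band=band, mu_eff=t["mu_eff"], psf_fwhm_at_1mm=p1, psf_fwhm_slope=slope)
        for z, tgt in ((1.0, t["fwhm_1mm"]), (6.0, t["fwhm_6mm"])):
            got = fit_capillary_fwhm(render_capillary(z, m, PIXEL_MM, SHAPE), PIXEL_MM).fwhm
            print(f"  check z={z} mm: fitted {got:.4f} mm (target {tgt})")


if __name__ == "__main__":
    main()
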