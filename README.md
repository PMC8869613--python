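# stereonir

3D reconstruction of blood-vessel depth from stereo NIR-II (1000–1700 nm)
fluorescence images, plus a synthetic phantom bench for validating it.

## The problem

NIR-II fluorescence imaging sees vessels several millimetres deep in
scattering tissue, but a single camera produces a 2D projection. A minimal
route to depth is binocular stereo built from **one** InGaAs camera on a
translation stage: the camera acquires a left-eye and a right-eye view
separated by a baseline *b*, and the horizontal disparity *d = X_L − X_R*
of a vessel between the views encodes its distance

&nbsp;&nbsp;&nbsp;&nbsp;*Z ≈ b·f / d*,

with *f* the focal length and *d* in metric sensor units. The smallest
resolvable depth step for a disparity error Δp is

&nbsp;&nbsp;&nbsp;&nbsp;*D_r ≈ Z²·Δp / (f·b)*.

At the modelled geometry (*Z* = 450 mm, *b* = 40 mm, *f* = 35 mm, 20 µm
pixels) one pixel of disparity error is 2.9 mm of depth, so sub-pixel
matching is everything: a 0.6 mm depth resolution requires ~0.2 px
disparity accuracy.

The package implements the full pipeline a stereo fluorescence bench needs —

- **vessel enhancement**: multiscale Hessian (Frangi-type) vesselness and
  contrast-independent segmentation (`stereonir.enhance`);
- **stereo matching**: from-scratch semi-global matching (census and SAD
  costs, 4/8-path aggregation, sub-pixel refinement, left-right
  consistency) (`stereonir.sgm`);
- **triangulation**: disparity ↔ depth conversion and depth-resolution
  arithmetic (`stereonir.geometry`);
- **depth maps**: vessel-masked metric depth, per-vessel statistics, and
  the red–yellow–green–blue depth colouring (`stereonir.depth`);
- **a phantom simulator** standing in for the physical apparatus: tube
  scenes projected through the stereo optics with a calibrated
  1% Intralipid scattering model (depth-dependent attenuation and PSF
  growth per collection band) and detector noise (`stereonir.phantom`);
- **quantification**: line profiles, Gaussian FWHM fits, intensity-vs-depth
  curves, depth-recovery scoring (`stereonir.profiles`, `stereonir.analysis`).

It is written for imaging-methods researchers who want to reason about
stereo depth recovery in scattering media — baseline/optics trade-offs,
matching accuracy, band selection — without the bench.

## Worked example

`examples/02_two_layer_phantom.py` renders the canonical two-layer vessel
phantom (four 1 mm tubes: two 7.5 mm below the phantom top, two at 8.5 mm)
through the 1300-LP scattering model and reconstructs it:

```
per-vessel reconstruction (depths below the phantom top, mm):
  vessel 1: measured 7.53  true 7.5  (384 px)
  vessel 2: measured 8.46  true 8.5  (341 px)
  vessel 3: measured 7.50  true 7.5  (386 px)
  vessel 4: measured 8.47  true 8.5  (361 px)
upper layer mean: 7.52 mm (true 7.5)
lower layer mean: 8.47 mm (true 8.5)
layer separation: 0.95 mm (true 1.0)
pixelwise depth RMSE: 0.16 mm
```

Each vessel's depth comes from averaging sub-pixel disparities over a few
hundred mask pixels; the 1 mm layer gap — only 0.35 px of disparity — is
recovered to 0.05 mm. The other examples cover the rig arithmetic
(`01_stereo_geometry.py`), the simulated Intralipid capillary depth series
with its intensity/FWHM trade-off between the 1100-LP and 1300-LP bands
(`03_intralipid_depth_series.py`), and the matcher's sub-pixel accuracy on
known shifts (`04_subpixel_matching.py`).

A thin CLI mirrors the library for shell use:

```sh
stereonir simulate --scene two_layer --band LP1300 --seed 4 --out sim/
stereonir run sim/left.tif sim/right.tif --out out/
stereonir analyze fwhm --band LP1300
```

`stereonir run` writes the enhanced pair, the disparity and depth maps
(32-bit float TIFF, NaN = invalid), the colour-coded depth render (PNG) and
the per-vessel CSV.

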