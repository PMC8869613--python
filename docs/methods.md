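# Methods

This note records the models behind `stereonir`, the parameters that
matter, and the choices made where the design was genuinely open.

## Stereo geometry

The rig is one pinhole camera translated horizontally by a baseline *b*
(default 40 mm), imaging a scene at reference distance *Z₀* (default
450 mm) with focal length *f* = 35 mm and pixel pitch 20 µm. Because the
second view is a pure horizontal translation of the same camera, epipolar
lines are image rows and no rectification is applied; input pairs are
assumed row-aligned.

Triangulation uses the small-angle relation *Z = b·f/d* with *d* the metric
disparity (pixel disparity × pitch). Reported depth is signed mm relative
to a configurable reference plane, `depth = Z₀ + offset − Z`, so negative
means deeper — the convention vascular depth maps are displayed in. The
theoretical depth resolution is *D_r = Z²·Δp/(f·b)* for disparity error Δp;
its exact scaling laws (∝Z², ∝1/b, ∝1/f, ∝Δp) are asserted in tests.

The pixel pitch is not a property of the optics alone and is a declared
configuration parameter; 20 µm is the typical pitch of the 640×512 InGaAs
sensor class modelled here. At this geometry one pixel of disparity is
≈2.89 mm of depth and a 1 mm depth step is ≈0.35 px of disparity, which
frames everything below: per-vessel depth accuracy hinges on sub-pixel
matching plus averaging over each vessel's mask.

## Vessel enhancement

Standard two-eigenvalue 2D vesselness: at each scale σ the σ²-normalised
Hessian eigenvalues (|λ₁| ≤ |λ₂|) give blobness R_B = λ₁/λ₂ and
structureness S = √(λ₁²+λ₂²), combined as
`exp(−R_B²/2β²)·(1−exp(−S²/2c²))`, zeroed where λ₂ ≥ 0 for bright
vessels, maximised over scales. Defaults: β = 0.5, c = half the maximum
structureness ("auto"), scales σ ∈ {1, 2, 3, 4} px spanning the radii of
millimetre vessels at the rig's ≈0.26 mm/px object-space sampling.
Hessian filtering is delegated to scikit-image (with replicate boundary
handling so constant images stay silent); the functional itself and a
cross-check against scikit-image's reference vesselness filter are local.

**Segmentation.** The vesselness response scales with vessel contrast, and
attenuation in scattering media makes deep vessels several-fold dimmer
than shallow ones in the same frame, so a single global Otsu threshold
reliably drops the dim class. The default segmentation is therefore
*adaptive*: candidate structures are found by an Otsu cut in log-response
space (background and vessel responses differ by orders of magnitude),
then each connected candidate is cut at half its own peak response. The
half-maximum cut mirrors the FWHM convention used for vessel widths and
makes the mask contrast-independent; global `otsu`/`multiotsu` and fixed
thresholds remain available. Components below `min_component_size`
(default 50 px) are dropped to suppress speckle.

## Semi-global matching

Costs: census transform (7×7 window, 48 comparison bits, Hamming
distance) or block SAD (7×7 box mean, normalised to the census numeric
scale so one penalty pair serves both). Aggregation follows the standard
SGM recurrence over 8 (or 4) scanline directions with P1 = 10, P2 = 120;
winner-take-all ties break toward the smaller disparity. The disparity
search window is derived from the configured geometry (*b·f/(Z₀ ± z_span)*
in pixels, padded by 2 px) rather than guessed. Validity combines a
geometric bound (the matched column must exist) with a left-right
consistency check (tolerance 1 px).

**Sub-pixel refinement** interpolates the cost minimum from the triple
(d−1, d, d+1). Two estimators are provided: the three-point parabola, and
an equiangular "vee" (two-line) fit that is exact when the cost is
piecewise linear in the sub-pixel shift — which block costs are, to first
order, around a pure translation. Offsets are clamped to (−½, ½);
boundary disparities are never refined.

Two accuracy-driven defaults deviate from the more common census-only
arrangement, both established with the package's own rendered ground
truth:

1. **Refine on the raw volume.** Path aggregation regularises the integer
   winner but skews the cost valley around it (the P1/P2 terms are not
   symmetric in the sub-pixel offset); interpolating the aggregated volume
   left systematic per-vessel biases up to ≈0.2 px at unfavourable
   fractional disparities. Refining the *raw* cost volume at the
   aggregated winner removes this (<0.03 px noise-free).
2. **Hybrid census+SAD cost (default).** Census is invariant to monotonic
   intensity changes, so dim deep vessels and bright shallow ones match
   equally robustly at the integer stage; but its Hamming-distance valley
   is a poor interpolation target. The default therefore aggregates census
   costs for the integer disparity and refines on the raw SAD volume,
   whose valley tracks the photometric profile. With a single translating
   camera the two views share illumination and detector response, so SAD's
   photometric sensitivity costs nothing. Pure `census` and `sad` modes
   remain available.

With these defaults the matcher recovers fractional shifts of smooth
textures to ≲0.05 px mean error, and per-vessel mean disparities on
rendered phantoms to ≲0.1 px under noise — comfortably inside the ≈0.2 px
needed for 0.6 mm depth resolution.

## Phantom simulator

The simulator replaces the physical bench. Tubes are cylinders along 3D
polylines; their transverse emission profile is the peak-normalised chord
length of the bore, `√(1−(s/r)²)` — not a Gaussian — so width arithmetic
follows physical geometry (the bare chord profile has half-maximum width
r·√3). Each view is a pinhole projection with the camera centre displaced
±b/2, rendered in continuous coordinates so a tube's disparity equals the
triangulation prediction to <0.05 px before blur and noise (asserted by a
centroid test).

**Medium model.** Each collection band carries an effective attenuation
coefficient and a linearly growing Gaussian PSF:
intensity ∝ exp(−μ_eff·(z−1 mm)) relative to 1 mm depth, FWHM(z) =
FWHM₁ + slope·(z−1 mm). The defaults are calibrated to image-domain
observables of a fluorophore-filled capillary (inner diameter 1.1 mm) in a
1% Intralipid analogue, not to literature optical coefficients:

| band | μ_eff (mm⁻¹) | PSF FWHM at 1 mm | slope (mm/mm) | anchored to |
|---|---|---|---|---|
| 1100-LP | ln2/3 ≈ 0.231 | 1.761 mm | 1.459 | half-intensity at 4 mm; fitted FWHM 1.87→9.08 mm over 1–6 mm |
| 1300-LP | ln2 ≈ 0.693 | 1.071 mm | 0.257 | half-intensity at 2 mm; fitted FWHM 1.25→2.44 mm |
| 1400-LP | 1.0 | 0.86 mm | 0.21 | qualitative extrapolation (no measured series) |

The PSF numbers are solved by `scripts/calibrate_medium.py`, which inverts
the package's own render → transverse profile → Gaussian fit pipeline, so
the calibration is auditable end to end. The capillary bench is rendered
on a plain 0.1 mm/px metric grid (fixed magnification, imaging from
above); stereo scenes apply the medium per tube at that tube's optical
depth with the PSF converted through the local object-space pixel size.

**Noise and exposure.** Detector noise is Poisson shot noise (photon_scale
= 0.25 detected photons per count, i.e. variance = mean/0.25) plus
Gaussian read noise (100 counts), clipped and quantised to 16 bits —
parameters chosen as typical of cooled InGaAs cameras. By default the
renderer auto-exposes each scene so the brightest structure reaches 30 000
counts, as a bench operator sets integration time; fixed absolute scaling
is available. All randomness is seeded and bit-reproducible.

**Canonical scenes.** `make_two_layer_phantom()` builds the four-tube
two-layer phantom: 1 mm tube diameter, 40×30 mm lateral field, layers 7.5
and 8.5 mm below the phantom top (1 mm gap). The scattering-medium surface
sits 3.5 mm above the upper layer so the layers lie at optical depths of
4 and 5 mm, matching the phantom's ~5 mm imaging depth; the exact branch
angles of the layout are qualitative. `make_tube_pair_scene(gap)` builds
the compact two-tube scene used for depth-resolution sweeps.

**ROI for intensity-vs-depth.** The averaging ROI must capture the
depth-broadened PSF, otherwise blur loss masquerades as attenuation; the
capillary-curve helper dilates the bore footprint by twice the band's
deepest PSF FWHM (>99% flux capture), so the normalised curve measures
attenuation alone. `intensity_vs_depth` itself accepts any explicit ROI.
The half-intensity depth is read off the curve by piecewise-linear
interpolation at the first crossing of 0.5.

## Quantification

Line profiles are sampled by bilinear interpolation and averaged across a
configurable perpendicular width. FWHM comes from a bounded least-squares
Gaussian fit (amplitude = max−min, centre = argmax, σ from the second
moment, offset = min as deterministic initialisation); non-convergent fits
are returned flagged, never as silent numbers. FWHM = 2√(2 ln 2)·σ holds
to machine precision by construction. Depth-recovery scoring reports
per-vessel bias, pixelwise RMSE, valid fraction, and the layer separation
as the difference of per-layer mean depths — invariant to any common-mode
depth offset.

## Problem sizes and runtime

The canonical phantom renders at the full 512×640 sensor. The
depth-resolution sweep (5 gaps × 20 seeds) uses the compact tube-pair
scene on a 256×384 frame: each vessel still covers a few hundred mask
pixels, which is what sets the per-vessel averaging gain, so the measured
resolution is representative while the sweep stays in the minutes range on
one CPU. Depth colouring uses equally spaced red–yellow–green–blue
anchors; per-vessel statistics default to the mean (median optional).

## Limitations

- The medium model is a per-tube attenuate-and-blur approximation; it does
  not model radiative transfer, depth-dependent asymmetric PSFs,
  autofluorescence background, or inter-tube shadowing.
- The simulator's clean backgrounds and smooth tubes are kinder to
  matching and segmentation than in vivo tissue; passing phantom tests
  demonstrates the pipeline's geometry and sub-pixel machinery, not
  in vivo robustness.
- The two views are assumed perfectly row-aligned (ideal stage travel); no
  rectification or vertical-disparity estimation is provided.
- Occlusion handling is limited to left-right consistency; dense
  non-vessel scene depth is out of scope, as are multi-view (>2)
  extensions and centerline vectorisation.
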