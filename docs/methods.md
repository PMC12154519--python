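# Methods

`pinholesim` models a portable planar gamma camera for post-therapy
Lu-177 imaging: a single channel-edge pinhole in a tungsten plate that
projects a minified, inverted image of the activity distribution onto a
small pixelated scintillator.  This note records the model, its parameters,
the numerical choices, and what the model deliberately leaves out.

## Camera model

The pinhole centre is the coordinate origin; the pinhole axis is z, the
object sits at z > 0, the detector plane at z = −b_det.  Default geometry
(config-overridable throughout):

| parameter | default | notes |
|---|---|---|
| pinhole diameter d | 1.2 mm | |
| acceptance angle a | 94° | full opening angle of the aperture cones |
| channel height | 1 mm | see "channel height" below |
| plate/shield thickness | 5 mm | tungsten |
| object-to-pinhole b_obj | 100 mm | minification b_obj/b_det = 5 |
| pinhole-to-detector b_det | 20 mm | |
| detector | 41×41 GAGG crystals, 1×1×5 mm, 0.2 mm septa | 49.0 mm sensitive span in a 50 mm side |
| optical guide | 1 mm | geometric bookkeeping only, not attenuated |

The aperture is a solid of revolution: a cylindrical channel of diameter d
and the stated height, flanked by two cones opening at a/2 until they reach
the plate faces.  `aperture_path_length` computes the exact tungsten chord
of any ray through this solid (piecewise-quadratic root finding; validated
against 1 µm ray marching), which in one term covers clean passage, edge
penetration and flat-shield leakage.

**Channel height.**  The prototype's descriptions are contradictory (5 mm in
the design narrative, 1 mm in the specification table).  A 5 mm channel
filling the 5 mm plate would collimate the bore to atan(1.2/5) ≈ 13.5° and
shrink the usable field to ~48 mm, which is inconsistent with the camera's
250 mm field of view and with every wide-field phantom protocol, so the
package defaults to the 1 mm value; both are available in the config.

**Field of view.**  The conventional "active FOV" is the detector side times
the minification: 250 mm.  The 94° acceptance cone geometrically subtends
only 2·b_obj·tan(47°) ≈ 214.5 mm, but rays slightly outside it cross a thin
wedge of tungsten and are only attenuated, not blocked, so the cone
*vignettes* the field rather than truncating it.  `active_fov` reports both
sides and which constraint binds; the vignetting is exactly why a
flood-field correction is part of the evaluation pipeline, and why the
flood's uniformity CV is large (below).

## Emission model

Lu-177 gammas are represented as a discrete line table (ENSDF/NuDat
intensities): 112.95 keV (6.17 %/decay), 208.37 keV (10.36 %/decay) and the
minor 71.64/136.72/249.67/321.32 keV lines (together < 0.6 %/decay).  Each
decay emits each line independently with probability equal to its intensity.
Betas, conversion electrons, bremsstrahlung and X-ray fluorescence are not
transported: the imaging windows only use the gamma peaks.  The table is
replaceable in code or from a two-column CSV.

Energy windows are unions of inclusive closed intervals built as
E·(1 ± f) around one or more peaks, merged where they overlap: ±10 % about
113 keV gives 101.7–124.3 keV; ±35 % about both peaks merges into a single
73.45–280.8 keV acceptance interval.

## Transport

Photons are tracked analytically from emission point to detector:

1. **Direction.** Either uniform over 4π, or uniform inside a per-photon
   cone aimed at the pinhole, with the cone's solid-angle fraction
   (1 − cos α)/2 carried as a statistical weight.  With
   `cone_target="detector"` the cone covers every direction that can reach
   the detector (computed from the detector corners per emission point plus
   a 2° margin), so the weighted estimator is unbiased — scatter-free
   transport admits no detected photon outside that cone.  With
   `cone_target="aperture"` the cone only covers the aperture mouth plus a
   2 mm penumbra: ~30× cheaper per detected event, but blind to shield
   leakage; it is used for relative image-structure studies (flood shape,
   Derenzo, ROI ratios), never for absolute sensitivity.
2. **Phantom attenuation.** exp(−Σ μ(E)·ℓ) along the ray from the emission
   point to the pinhole plane.  Convex analytic regions contribute exact
   chord lengths (interval union handles pairwise overlaps, the most the
   generators produce); voxel μ-maps are ray-marched at half the voxel size.
   Survival is sampled, not weighted, so count grids stay Poisson.
3. **Aperture.** Survival with probability exp(−μ_W(E)·path) through the
   aperture plate (or a hard cut at zero path when penetration is disabled).
4. **Detector.** Absorption with the slab probability
   1 − exp(−μ_det(E)·t/cos φ) at incidence angle φ; recorded energy blurred
   with Gaussian FWHM(E) = f_ref·sqrt(E_ref·E), default 10 % at 122 keV
   (typical pixelated-scintillator performance; the blur model is a default,
   not a fitted value).  Hits are binned by the pixel whose crystal
   footprint contains them; hits on the 0.2 mm septa are discarded
   (fill factor (1/1.2)² ≈ 0.69).

Lines whose blurred energy cannot reach any requested window (6σ rule) are
skipped before transport — pure variance reduction, exact to ~1e−9.

Attenuation coefficients for water, tungsten, GAGG and CsI(Na) are embedded
as small grids of standard-compilation (NIST) mass-attenuation values,
log-log interpolated; all tables are overridable via
`materials.register_material`.

**What is not modelled, and what that costs.**  Compton scattering — in the
phantom, the collimator/shield, and the crystal — is excluded everywhere;
attenuation removes photons and nothing is re-emitted.  Optical transport,
PSPMT/readout effects, inter-crystal scatter, dead time and pile-up are also
out of scope.  Consequences, measured with this package's own runs:

* the absolute system sensitivity comes out near 1.6 cps/MBq, roughly a
  third of what full-physics simulation and measurement give for this
  camera class (≈5–6.5 cps/MBq): scattered transmission through the thin
  5 mm shield, collimator scatter and inter-crystal scatter all add counts
  the first-order model cannot produce;
* the flood field falls off faster towards the field edge than a
  full-physics flood (no scatter fill-in), so its profile CV is ~65 % over
  the illuminated field where scatter-inclusive models report ~20–35 %.

Relative quantities — minification, projection geometry, the inverse-square
depth ratio, rod resolvability, flood-corrected ROI ratios — are insensitive
to the missing scatter at the few-percent level, which is why the resolution
and depth-ratio protocols reproduce while absolute sensitivity does not.

## Phantoms

All generators place sources in the camera frame with the study activities:

* **flood**: uniform 250×250×10 mm water box, front face at 100 mm, 80 MBq
  (37 MBq experimental variant);
* **Derenzo-like**: 286×286×15 mm slab, six 60° sectors with rod diameters
  29/18.6/15.7/13/11.5/10 mm, triangular packing with centre spacing twice
  the diameter, rows of 1, 2, 3, … rods starting at twice the diameter from
  the centre and growing while rods fit the sector wedge and the slab,
  18.5 MBq per rod.  The sector layout (a classic hot-rod convention) is
  fully determined by the diameters and slab size and recorded in the
  phantom metadata;
* **point sources**: 1000 MBq in a 2 mm water sphere at offsets
  0/20/40/60/80/100 mm, 100 mm from the pinhole;
* **two-sphere**: 12.4 mm spheres at depths 100 and 125 mm, 370 MBq each,
  laterally offset ±25 mm (so the projections separate; the ratio metric is
  offset-insensitive to first order) in a 200 mm water box of 37 MBq;
* **rat-like**: four ellipsoids (left tumour, liver, bladder, right tumour)
  of 18.5 MBq each in a water body, surface separations 17 mm
  (tumour–liver) and 9 mm (bladder–tumour), bottom face at 100 mm.  This is
  a synthetic stand-in preserving separations and activities, not an
  anatomical rat;
* **voxel volumes**: raw little-endian float32 in z-y-x order plus a JSON
  sidecar (dims, voxel size, origin, semantics activity|mu) — a minimal,
  byte-order-documented interchange format.

Phantom self-attenuation uses the enclosing water body only; for the
two-sphere phantom the sphere volumes are also included via interval union.
The generators' totals are exact sums of their parts, and uniform sampling
within each primitive is tested against centroid convergence.

What the generators do not emulate: organ shapes, tissue heterogeneity,
scatter media outside the phantom, patient motion.  Tests passing on these
phantoms therefore validate geometry, counting statistics and the
evaluation pipeline — not anatomical realism.

## Evaluation pipeline

* **Flood correction** divides by the flood normalised to unit mean over
  reliable pixels, preserving the global count scale; flood pixels under 10
  counts are masked and propagate as NaN.  At desk-scale statistics the
  flood is additionally smoothed with a σ = 1 px Gaussian before division —
  the stand-in for the hours-long high-statistics flood of the laboratory
  protocol.
* **Sensitivity** is windowed counts/(duration × activity); cone-sampled
  runs use the weighted estimate with the summed-squared-weight error.
* **Resolvability**: profiles are taken through the centres of one rod row
  per Derenzo group (the innermost row with ≥ 3 rods; outer rows sit in the
  vignetted field edge), averaged over a band one projected rod diameter
  wide, lightly smoothed (3-sample moving average), then local maxima above
  20 % of the profile maximum are counted; the group resolves when the
  expected number of peaks appears and every inter-peak valley is ≤ 0.8 of
  the mean of its adjacent peaks.  All thresholds are arguments.
* **ROI ratios** use circles of each sphere's projected diameter
  (d·b_det/z) at the projected centres, comparing mean pixel values (the
  size-independent convention, which also reproduces the 0.64 inverse-square
  limit for point-like spheres); uncertainty is Poisson-propagated from raw
  counts.
* **Uniformity CV** is 100·std/mean of a profile, NaN-aware and
  scale-invariant.

## Problem sizes

Simulated acquisitions are scaled down from the laboratory protocol so the
suite and the reproduction script run on one CPU in minutes: the flood uses
1.2–4.8×10⁹ decays (10⁵–10⁶ accepted counts) instead of 4.3×10¹⁰, the
sensitivity run 0.12 s of a 1000 MBq source (≳10⁴ accepted events), the
Derenzo and two-sphere runs 0.3–0.5 s of their stated activities.  Scaling
down durations at fixed activities changes only the statistical errors, all
of which are propagated in the reported values.

## Known limitations

* Absolute sensitivity and flood uniformity are systematically off from
  full-physics values for the reasons above; the package reports what its
  model computes and does not calibrate toward external numbers.
* Tungsten fluorescence, coincidence summing and decay-chain daughters are
  not modelled.
* The attenuation tables cover 60–662 keV; energies outside raise.
* Tomographic reconstruction, multi-pinhole geometries and DICOM/Interfile
  I/O are out of scope.
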