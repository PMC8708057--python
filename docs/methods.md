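# Methods

`edemaquant` estimates the volume of intraretinal fluid (macular edema) from
a raster of co-registered OCT B-scans and derives the standard ETDRS
tomography features from the same boundary detections.  This note documents
the model assumptions, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Scan model

An acquisition is a `width_mm x depth_mm` en-face rectangle (default
9 x 6 mm) sampled by `n_bscans` uniformly spaced B-scans (default 25).  Each
B-scan is an 8-bit depth-by-lateral image with row 0 on the vitreous
(anterior) side.  Physical pixel pitches travel in a sidecar `ScanGeometry`
config and are never inferred from the raster, which carries no metadata.

The inter-B-scan spacing defaults to `depth_mm / (n_bscans - 1)` = 0.25 mm.
Vendor metadata sometimes reports a spacing that is inconsistent with the
en-face extent; `spacing_mm` is therefore an explicit override rather than a
silently trusted value, and every volume scales linearly with it.

## Image pipeline

1. **Adaptive Wiener filter (5 x 5).**  The textbook local-statistics form:
   each pixel is shrunk toward its local mean by `max(v - noise, 0) / v`,
   with `v` the local variance and `noise` defaulting to the image-mean local
   variance.  It is built on `scipy.ndimage.uniform_filter` with reflect
   borders rather than `scipy.signal.wiener` because the latter zero-pads,
   which both darkens the frame edge and contaminates the global noise
   estimate; the two agree exactly on interior pixels for a shared noise
   power (this is a regression test).

2. **SNR balancing.**  `I_f = (I_0 - N) / (S - N)`, where `N` is the mean
   pixel value of a noise window in the vitreous (default: top-left 32 x 32)
   and `S` the mean of a signal window in tissue (default: the 32-column
   right-edge strip restricted to the central third of rows, a geometry-free
   stand-in for the retinal band).  Both are averaged over all B-scans of the
   stack, so one transform applies to the whole eye.  The mapping anchors the
   noise floor at 0 and the signal level at 1, which is what makes a single
   dark-intensity threshold transferable across scans of varying signal
   strength.  Outputs are clipped to [0, 1]: the affine map can exceed the
   range, and clipping keeps the downstream threshold meaningful.  `S <= N`
   is refused as degenerate contrast.

3. **Median despeckle (15 x 15).**  Rank median with reflect borders,
   removing salt-and-pepper impulses that survive the Wiener filter.

4. **Quality gate.**  The per-scan noise estimate (mean raw 8-bit value in
   the noise window) must be at or below a ceiling of 90 — inclusive — for
   every scan, otherwise the stack is rejected unless explicitly overridden.

## Boundary detection

Per A-scan (column), the axial profile is boxcar-smoothed over 5 rows and
differentiated.  The ILM is sought as the first run of rows from the top
where the gradient exceeds +0.05 per pixel (on the balanced scale); the RPE
as the first such run from the bottom with gradient below -0.05.  Each run
is reduced to its **gradient-weighted centroid** rather than its first
threshold crossing: smoothing spreads a step edge over ~15 rows, so the
first crossing sits several pixels anterior of the edge, while the centroid
of a symmetrically blurred step recovers the edge centre to sub-pixel
accuracy.  Boundaries are then median-smoothed across 15 columns and invalid
columns filled by linear interpolation; fewer than 50% valid columns raises
a boundary-failure error.

The 0.05 threshold is a compromise: the balanced retina-vitreous step has
slope ~1/15 per pixel after the 15 x 15 median, so the threshold must sit
below ~0.067 but above speckle-induced gradients.  It is config-exposed.

## Fluid segmentation

Within the ROI strictly between ILM and RPE, pixels with balanced intensity
below 0.1 are candidate fluid ("near-zero after balancing"; the threshold is
one tenth of the noise-to-signal dynamic range and config-exposed).  A
binary opening with a disk of radius 2 px removes thin bridges and speckle
residue, then connected components smaller than 25 px are dropped.
Thresholding precedes morphology; the minimum-size filter guarantees every
surviving component has at least `min_component_px` pixels.  Cross-section
area is pixel count times the in-plane pixel area
(`axial_mm_per_px * lateral_mm_per_px`); no printed device resolution is
hard-coded anywhere.

## Volume integration

With A_i the fluid area of the i-th B-scan and h the spacing,

    V = h/2 * (A_1 + A_n + 2 * sum_{i=2..n-1} A_i)

i.e. the composite trapezoidal rule (implemented via `numpy.trapezoid`; an
interval-wise brute-force sum serves as the test oracle).  The formula
generalises to any n >= 2.  Scans whose boundary detection fails are marked
invalid and their areas linearly interpolated from neighbours, preserving
the serial integration instead of discarding the eye.  Error on smooth area
profiles decays as O(h^2); for an ellipsoidal pocket the dominant error is
instead the sampling of the profile's kinks at the pocket edge, which is why
recovery accuracy degrades for pockets whose slow-axis extent approaches h.

## ETDRS features

Per-scan ILM/RPE separations (in um, via the axial pitch) are bilinearly
interpolated onto an isotropic en-face grid (default 50 px/mm; features move
< 1% above this resolution, a tested property).  The ETDRS grid uses the
standard 1 / 3 / 6 mm diameters — central disc, inner ring of 4 quadrants,
outer ring of 4 — whose areas sum to pi * 3^2 = 28.3 mm^2 exactly.  CFT is
the **mean** thickness of the central disc (whether devices report mean or
minimum varies; mean is the common subfield convention), CFV the central
sector volume, TRV the sum of all 9 sector volumes.  Sector volume is mean
thickness x nominal sector area (device convention), not voxel summation,
so TRV = mean thickness x 28.3 mm^2 holds exactly on uniform maps.  The
fovea defaults to the grid centre (the raster is assumed fovea-centred);
an explicit centre can be passed.  A 6-mm grid on a 6-mm slow axis touches
the map edge: truncated sectors average the available pixels and warn.

## Statistics layer

* **ICC** between manual and automated areas: two-way random effects,
  absolute agreement, single measure — ICC(2,1) — with an F-based 95% CI
  (delegated to `pingouin`; a hand-written ANOVA oracle checks it to 1e-6).
* **Regression thresholds**: OLS of a tomography feature on edema volume
  over eyes with EV > 0.  The intercept is the feature value at zero
  detectable fluid — the scanner's effective detectability threshold for
  that feature.  A zero-variance feature returns the degenerate r = 0,
  p = 1 instead of erroring.
* **Kruskal-Wallis + Conover-Iman**: tie-corrected omnibus H (scipy), then
  pairwise t statistics on the pooled ranks with the (N-1-H)/(N-k) variance
  deflation and df = N-k, Holm-adjusted (no installed package provides the
  Conover post hoc, so it is implemented here).  All-identical data returns
  H = 0, p = 1.
* **Normality**: composite KS with estimated mean/SD (Lilliefors form); the
  p-value comes from a seeded Monte-Carlo null (each simulated sample
  standardised by its own moments), making it exact up to simulation error
  rather than table interpolation.
* **Median CIs**: distribution-free symmetric order-statistic intervals
  from the binomial(n, 1/2) distribution, conservative by construction.
* **Response classification** from a visit series (date, CFT, injection
  flag), first match wins: treatment-naive (no injections); responder
  (>= 100 um CFT drop after the first or second injection, before the next
  one); recurrent (> 100 um rise vs the previous visit after >= 60
  injection-free days — "two months" read as 60 days); non-responder
  otherwise.  The final else-branch makes the rule set total: eyes with one
  or two injections and neither response nor rebound are read as persistent
  edema, hence non-responder.

## Synthetic data

The phantom generator emulates the geometry the pipeline assumes: a dark
vitreous, a bright retinal band between flat/tilted/foveally-dipped ILM and
RPE surfaces, dark choroid, and non-overlapping ellipsoidal pockets of dark
fluid.  Ground truth (masks, per-scan ellipse-slice areas
`pi*a*c*(1 - d^2/b^2)`, total volume `4/3*pi*a*b*c`) is analytic and
computed before noise, so the volume oracle is independent of any
rasterisation.  Speckle is multiplicative Gaussian `(1 + sigma*n)` clipped
to [0, 255] — simple, but sufficient to exercise the filters — and impulse
noise sets a fraction of pixels to 0 or 255.  Pocket overlap is rejected by
a conservative bounding-box test to keep the analytic volume exact.

What phantoms do **not** emulate: real speckle statistics (Rayleigh-like,
correlated), intra-retinal layering, vessel shadows, motion artefacts,
irregular pocket shapes, or subretinal fluid.  Passing the recovery checks
therefore validates the geometry and numerics of the pipeline, not its
clinical segmentation accuracy.

The cohort generator draws per-response-group log-normal edema volumes
around the group medians (responder 3.65, non-responder 3.93, recurrent
4.675, treatment-naive 1.604 mm^3; sizes 60/63/26/29; optional 19-eye
zero-EV arm) and couples CFT/CFV/TRV to EV linearly
(`feature = intercept + slope*EV + noise`) with intercepts 386.06 um /
0.30 mm^3 / 9.06 mm^3 and slope/noise pairs chosen once to produce moderate
(r ~ 0.4) and stronger (r ~ 0.65) correlations.  These defaults are the
generator's definition of a realistic treated-DR cohort and are not tuning
knobs; the regression-threshold machinery is validated by coverage (the
true intercept falls in the 95% CI at the nominal rate), not by matching
any particular cohort's point estimates.

## Problem sizes

Full-resolution validation phantoms use 25 B-scans of 496 x 512 px at
3.87 um axial / 17.58 um lateral pitch (a Spectralis-like raster); unit
tests use a coarser 200 x 256 raster (12 um / 35.16 um) with the same 9 x 6
mm footprint so that filter windows and pockets keep their physical
meaning.  Recovery phantoms span 0.1-2 mm^3, the range reported for
macular fluid by prior volumetric studies.  Intercept-coverage checks use
500 cohort replicates; rank-test calibration uses 2000 null replicates of
4 x 15 observations.

## Known limitations

* The signal-window default (central third of rows) assumes the retina
  crosses mid-image at the right edge; grossly decentred scans need an
  explicit window.
* Boundary detection assumes the strongest first gradient runs belong to
  ILM/RPE; dense epiretinal membranes or detachments would defeat it.
* The segmentation threshold is global per eye; focal shadowing can create
  false-positive dark regions inside the ROI.
* Volume error grows for pockets with slow-axis extent near the B-scan
  spacing (aliasing of the area profile); 25 scans over 6 mm resolve
  pockets of b >~ 0.5 mm well.
* ETDRS sector naming (nasal/temporal) ignores eye laterality; quadrant
  volumes are correct, labels may be mirrored for left eyes.
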