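# edemaquant

Quantifies **diabetic macular edema** from OCT B-scan rasters.  Given a
stack of co-registered 8-bit B-scans covering a 9 x 6 mm macular field, the
pipeline denoises and SNR-balances each scan, delimits the retina between
the inner limiting membrane (ILM) and the retinal pigment epithelium (RPE),
segments the dark intraretinal fluid pockets, and integrates the per-scan
cross-section areas into an **edema volume (EV)**.  It also derives the
standard ETDRS tomography features — central foveal thickness (CFT),
central foveal volume (CFV) and total retinal volume (TRV) — from the same
boundary detections, and ships the statistics used to analyse such cohorts:
ICC agreement between manual and automated segmentation, zero-edema
regression thresholds, Kruskal-Wallis/Conover group comparisons, and
anti-VEGF treatment-response classification.

It is aimed at retina researchers who have raster exports (PNG/TIFF) plus
scan geometry, rather than access to a vendor's proprietary volume format.

## Method

Per B-scan: adaptive Wiener filter (5 x 5) → SNR balancing
`I_f = (I_0 - N)/(S - N)` with the noise level `N` and signal level `S`
estimated from fixed windows and averaged over the stack → 15 x 15 median
despeckle → ILM/RPE as the first supra-threshold axial-gradient runs from
the top and bottom of each A-scan → fluid = pixels with balanced intensity
< 0.1 strictly between the boundaries, cleaned by binary opening and a
25-px minimum component size.  With A_i the fluid area of the i-th of n
B-scans and h the inter-scan spacing,

    EV = h/2 * (A_1 + A_n + 2 * Σ_{i=2}^{n-1} A_i)   [trapezoidal rule]

Stacks whose per-scan noise estimate exceeds 90 (8-bit units) are rejected
by a quality gate.  See `docs/methods.md` for assumptions and numerical
details.

## Worked example

Phantom scans with an analytically known ellipsoidal pocket (semi-axes
0.8 x 1.5 x 0.3 mm, volume 4/3·π·abc = 1.5080 mm³) run end to end:

```python
from edemaquant import (Ellipsoid, PhantomSpec, generate_phantom,
                        quantify_stack)

pocket = Ellipsoid(center_x_mm=4.5, center_y_mm=3.0, center_z_mm=0.87,
                   a_mm=0.8, b_mm=1.5, c_mm=0.3)
spec = PhantomSpec(n_rows=496, ilm_row=100, rpe_row=350,
                   pockets=(pocket,), seed=1)
stack, truth = generate_phantom(spec)
result, record = quantify_stack(stack)
print(f"analytic  EV = {truth.analytic_volume_mm3:.4f} mm^3")
print(f"recovered EV = {result.edema_volume_mm3:.4f} mm^3")
print(f"CFT = {record.cft_um:.1f} um, TRV = {record.trv_mm3:.2f} mm^3")
```

prints

```
analytic  EV = 1.5080 mm^3
recovered EV = 1.4838 mm^3
CFT = 971.4 um, TRV = 27.46 mm^3
```

i.e. the pipeline recovers the true fluid volume to within 1.6% on a
noise-free phantom; the CFT of ~971 um is the phantom's 250-px retinal band
at 3.87 um/px, and TRV is that thickness times the 28.3 mm² ETDRS
footprint.

The same flows are available from the shell:

```
edemaquant simulate --seed 1 --out phantom/
edemaquant volume  --stack phantom/bscans --config phantom/geometry.yaml --out result.csv
edemaquant segment --stack phantom/bscans --config phantom/geometry.yaml --out masks/
edemaquant etdrs   --stack phantom/bscans --config phantom/geometry.yaml --out etdrs.json
edemaquant stats   --table cohort.csv --seed 0
```

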