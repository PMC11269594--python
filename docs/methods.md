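# Methods

`musclemorph` automates two routine readouts in skeletal-muscle research:
the diameter of cultured myotubes (the in-vitro atrophy/hypertrophy
readout) and the cross-sectional area (CSA) and metabolic type of muscle
fibers on immunostained histological sections.  Both pipelines are built
from the same marker-controlled-watershed toolbox; this note records the
models, the parameter semantics, and the design decisions that were
genuinely open.

## Shared morphological toolbox

**Directional line filtering.**  An image is filtered with a digital line
structuring element of length *L* at each of *n* orientations
θ_k = k·180°/n, and the per-orientation results are combined per pixel.
The line is the Bresenham segment between the rounded endpoints at
±(L−1)/2, so diagonal lines contain slightly fewer pixels than *L* (the
usual digital-line behaviour).  Two combinations are used:

* *min over directional medians* — keeps only structures that look line-like
  in **every** orientation; removes speckle and thin spurious ridges
  (used on the myotube probability map);
* *max over directional medians* — keeps structures that look line-like in
  **some** orientation; enhances curvilinear networks and bridges gaps up to
  roughly *L*/2 along the structure (used on the fiber outline stain).

Medians over an even number of footprint pixels take the upper median
(rank ⌊n/2⌋, 0-based), the convention of `scipy.ndimage.median_filter`,
which the test oracles also implement.  Greyscale closings are computed on
an edge-replicated canvas padded by twice the footprint radius, so the
extensivity of closing (output ≥ input) holds on the whole raster; a
single-stage implementation with clamped indices would violate it near the
border.

**Extended minima and minima imposition.**  Extended minima with tolerance
*h* are the regional minima of the h-minima transform — connected basins
whose dynamic (depth below the lowest escape ridge) is at least *h* —
computed as morphological reconstruction by erosion of `img + h` over
`img` followed by regional-minima extraction, with 4-connectivity.  (The
residue shortcut `rec − img ≥ h` used by some libraries yields a different,
larger set; the reconstruction-plus-minima form is the one the
marker-based segmentation needs.)  Minima imposition reconstructs
`min(img + 1, fm)` by erosion over the marker function `fm`; the unit
shift assumes grey-level-scaled data.  A constant image is one basin
covering the raster.

**Marker-controlled watershed.**  Implemented in the package because its
tie-breaking must be fully specified for reproducibility and for exact
oracle testing: Meyer flooding on the minima-imposed relief, 4-connected,
with queue priority equal to the *flooding level* (the running maximum of
relief values along the flood path) and first-in-first-out age as the tie
break; markers are seeded in raster order, and every pixel joins the basin
that reaches it first, so watershed ridge pixels belong to the
first-reached basin.  The result is a partition: one label per marker
component, no unlabeled pixels.  An independent level-bucket
implementation in the test suite reproduces it bit for bit on random
rasters.

**Geodesic elongation.**  Per label: the geodesic diameter — the longest
within-region path length under chamfer (5, 7, 11)/5 weights, estimated by
the standard two-sweep (start at the innermost point, i.e. the maximum of
the Euclidean distance transform; find the geodesically farthest pixel;
measure the maximum distance from there) — divided by the diameter of the
largest inscribed disk (twice the maximum of the distance transform).
Distances are kept as integers scaled by 5, so results are exact and
independent of relaxation order; a one-pixel label is defined as 1.
Values are ≈ 1 for disks and ≈ length/width for straight or bent tubes,
which makes the measure a good tube-versus-blob discriminator.

**Morphometry.**  Area is the exact pixel count × pixel_size²; perimeter
is the 4-direction Crofton estimate; orientation is the ellipse-fit
major-axis angle from the central moments, in [0°, 180°) with ties broken
as 0°; the minimum Feret diameter comes from rotating calipers over the
convex hull of the pixel *squares* (centers ± 0.5), so an n-pixel-wide bar
measures exactly n pixels.

## Myotube pipeline (cells)

Inputs are 8-bit phase-contrast-style fields plus a 32-bit centerline
probability map.  The map normally comes from an external detector; a
model-free multi-scale Hessian ridge filter (maximum Sato tubeness over
σ ∈ {2, 4, 8} px) is built in as a fallback.  The field is cropped to a
square (top-left anchor by default) and a 512 × 512 working copy is used
for the probability stage; all measurements happen on the cropped original
raster, with the refined map upsampled back (bilinear).

The refined map (directional closing min/10/15, then directional median
min/5/15, thresholded at 30000/65535 of the probability range) gives the
candidate *frame*.  The frame is dilated by the border pad (default 5 px)
so it reaches the cell border; inside it the prepared image is the white
top-hat of the original (disk radius default 10 px); outside it the
raster is covered with a *noise ceiling* — the grey-range maximum plus
clipped Gaussian noise of sd `noise_sd` (default 15, seeded).  In the
inverted relief the ceiling becomes one deep exterior basin whose marker
lies outside every frame; segmentation keeps only basins whose extended-
minima marker (tolerance 35) intersects the dilated frame, so nothing
outside a candidate region can survive.  Additive noise on the original
values was considered and rejected: it does not suppress the basins of
off-target structures, which is the stated purpose of the step.

**Parameter sizing rule.**  The top-hat radius and the border pad must be
at least the largest expected tube half-width (in pixels on the
measurement raster): the top-hat must erase the tube in its opening for
the tube body to appear bright, and the frame must cover the full tube
for its basin marker to be retained.  The defaults (10 and 5 px) suit
tubes up to ~20 px wide; the synthetic suite (widths 10–30 µm at
0.548 µm/px, i.e. 18–55 px) therefore runs with both set to 30 px.

Labels are trimmed by area (750–120 000 µm², inclusive), border contact,
and geodesic elongation (6–30, inclusive).  Each surviving myotube is
closed (disk radius 2), hole-filled, and measured: the centerline is the
longest geodesic path through the skeleton (endpoints = skeleton pixels
with exactly one 8-neighbour; the longest path ignores short spurs),
lightly smoothed and resampled by a cubic spline at arc-length fractions
1/10 … 9/10 — nine interior stations, avoiding end-cap bias — and the
diameter at each station is the mask chord along the normal to the spline
tangent (nearest-pixel sampling at 0.25 px steps, so boundary-pixel
extents are included).  The record carries the nine diameters, their
arithmetic mean, the area and the ellipse orientation.  A label whose
skeleton has fewer than two endpoints (e.g. a ring) is rejected with a
diagnostic rather than silently measured.

## Fiber pipeline (histo)

Inputs are co-registered single-channel files: an outline stain (laminin
or dystrophin) and myosin channels (type I, type IIA, optional IIX),
matched across folders by sorted filename.

The outline channel is optionally edge-filtered (3 × 3 Sobel magnitude,
for weak or heterogeneous stains), then directional-median filtered
(max-combine, length 20, 15 orientations) and contrast-normalized with an
auto-parameterized CLAHE: block size = round(width/5), 256 bins,
max slope = (mean grey/60)/0.05 floored at 1 (a black image degenerates
to a no-op).  The CLAHE wrapper maps the slope to the clip limit as
clip ≈ slope · tile_pixels / bins, normalizes the input to [0, 1] and
rescales the output to the input range; slope 1 is an identity to within
one grey level.

Watershed markers are the extended minima (tolerance 20) of the
**pre-CLAHE** median stage: the tolerance is calibrated in original grey
levels, and applying it after CLAHE is unstable — with a typical slope of
15–30, CLAHE amplifies the residual noise of flat fiber interiors past
any fixed tolerance and shatters each fiber into thousands of minima.
The flood itself runs on the CLAHE relief.  Basins are trimmed by area
(2000–200 000 µm²), border contact and elongation (> 4 dropped), then each
label is eroded by a 3-px disk so intensity measures never touch the
boundary band.  The spreadsheet reports the pre-erosion area (erosion
would bias CSA low by roughly perimeter × 3 px) and intensities from the
eroded pixels; `report_eroded_area` flips the former.

Fiber typing: per fiber, the mean grey on the type-I and type-IIA
channels gives the score Δ.  In `raw` mode Δ = g_I − g_IIA (grey levels)
with thresholds ±40; in `normalized` mode (default)
Δ = (g_I − g_IIA)/(g_I + g_IIA + 10⁻⁶) ∈ (−1, 1) with thresholds ±0.2.
Δ below the low threshold → type IIA, above the high threshold → type I,
otherwise (boundary values included) → type IIB/IIX.  The two threshold
systems agree when g_I + g_IIA ≈ 200; the normalized score is
exposure-invariant and is the default.  Intensities are measured on the
raw channels: running the adaptive CLAHE on the myosin channels before
measurement was evaluated and rejected as the default, because tile-local
equalization makes a fiber's mean grey depend on its neighbours' classes
and misclassifies borderline fibers; it remains available
(`raw_intensities=False` / `--clahe-intensities`) for sections with strong
staining heterogeneity, which is the scenario it exists for.

A fiber called IIB/IIX whose g_I and g_IIA both exceed their floors
(default 100 grey) is flagged "Hybrid?" — co-expression of both myosins
pushes Δ into the IIB/IIX window, so such calls need manual confirmation;
the flag is advisory only.  With a type-IIX channel supplied the pipeline
runs in measurement-only mode: three intensity columns, no type calls.

A file-based manual checkpoint writes the segmentation label raster to
disk, lets the user edit it, and re-imports it before measurement.

## Synthetic scenes

The generators emulate the geometry and intensity statistics of the two
acquisition types at the default calibration of 0.548 µm/px; they do not
model optics (no PSF, no shading, no true phase-contrast physics), so
passing tests demonstrate the correctness of the measurement chain, not
robustness to real acquisition artifacts.

**Myotube fields** (default 640² px, 4 tubes): constant-width sweeps
along smooth random walks (heading noise 0.02 rad per 2-px step), widths
uniform in 10–30 µm, lengths in 100–250 µm restricted to 7–28× the width
so true elongations stay inside the trimming window; interior grey 160
over a textured background (grey 100, smooth component sd 6 at 25-px
scale, fine noise sd 3 — the low-noise regime), with a 2-px rim at grey
55 standing in for the phase halo.  The rim is centered on the true tube
boundary (one pixel inside, one outside), as a real halo straddles the
cell edge; the watershed crest splits the rim plateau down the middle, so
the recovered label boundary coincides with the truth.  The rim is also
rendered noise-free: it is the barrier the segmentation must find, and a
noisy rim makes the barrier height exactly tie with background
fluctuations, turning the basin boundary into an arbitrary queue-order
coin flip — a fixture must keep its own ground truth unambiguous.  The ideal probability map is
the rasterized centerline blurred with a σ = 2 px Gaussian, scaled to
[0, 1].  Truth stores the label raster, exact widths and centerlines.

**Fiber mosaics** (default 1024² px, 120 fibers): Lloyd-relaxed Voronoi
cells; the outline channel is a boundary band (width 4 px, grey 220 over
background 20) with an optional fraction knocked out in ~10-px arcs; each
myosin channel holds the per-class mean — class I (180, 30, 30), class
IIA (30, 180, 30), class IIB/IIX (30, 30, 180) across (I, IIA, IIX) —
plus Gaussian noise sd 10, so the class separation is 15 sd and both
threshold systems classify the noise-free model identically.  Truth
stores each fiber's class and exact CSA (band excluded).

## Validation suite and problem sizes

`scripts/acceptance.py` regenerates everything from a seed and reports:
median and minimum per-tube Dice and the median relative error plus
Pearson r of the mean diameter over 20 myotube fields (80 tubes);
fiber-type attribution accuracy and true-vs-measured CSA Pearson r over
four 120-fiber mosaics (~250 segmented interior fibers); and the
structural constants observed live (512-px working copy, nine stations).
These sizes keep a full run within a few minutes on one CPU while leaving
the statistics stable to well under the margins asserted in the tests.
The same benchmarks back the test suite, alongside exact-equivalence
tests of every operator against brute-force oracles on 200 random 16 × 16
rasters and bitwise-determinism checks of repeated seeded runs.

## Known limitations

* The centerline probability map is assumed given (file mode) or is
  approximated by a generic ridge filter; no learned detector is bundled,
  and the ridge fallback is weaker than a trained model on textured or
  low-contrast fields.
* Diameter accuracy is quantization-limited to roughly ±0.5 px per mask
  edge (≈ 0.5 µm at the default calibration); tubes narrower than ~6 px
  are not measured reliably.
* The watershed boundary is placed on ridge crests; for boundary bands of
  width > 1 px the fiber basin includes about half the band, so measured
  CSA is biased high by ≈ perimeter × band/2 (correlation with truth is
  unaffected; absolute CSA comparisons between protocols with different
  staining thickness are not).
* Hybrid-fiber identification is a flag, not a classification; rodent
  IIB vs IIX are not separated.
* Channel co-registration is assumed; there is no image registration.
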