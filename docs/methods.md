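# Methods

This note records the measurement model implemented by `molarmetrics`, the
design decisions taken where the procedure was genuinely open, the
synthetic-phantom conditions under which the package is verified, and the
known limitations.

## The measurement problem

The third-molar maturity index is I3M = (a + b) / c, where a and b are the
widths of the mesial and distal open root apices and c is the tooth height,
all read off a 256×256 crop of a mandibular third molar from a panoramic
radiograph.  The index is dimensionless, so the pixel scale cancels; the
decision rule classifies I3M < 0.08 as adult (≥ 18 y), otherwise minor.
Exact equality with the threshold is classified as *minor* — the
conservative direction in a safeguarding context — and the threshold is a
parameter throughout.

The input contract is a two-part instance segmentation: one *coronal*
polygon (crown-side mineralized tissue) and one *apical* polygon (root-side
mineralized tissue, shaped as canal walls with open apices).  Any
segmentation source satisfying this contract can feed the measurement; the
package itself neither trains nor requires a segmentation network.

## Vertical alignment

Both geometries start by rotating the mask pair so the coronal barycenter
sits directly above the apical one.  Barycenters are unweighted centroids
of the true pixels.  The rotation angle maps the coronal→apical barycenter
vector onto the downward vertical (atan2 supplies the extra half turn when
the crown starts out below the root); the rotation center is the midpoint
of the two barycenters, which keeps both regions in frame symmetrically.
Masks are resampled by bilinear interpolation of the binary indicator,
re-binarized at 0.5 — an approximation to area-coverage resampling.  This
choice replaces plain nearest-neighbor sampling because the structures that
carry the measurement (wall tips a few pixels across) suffer roughly half
the quantization jitter under coverage binarization; labels remain binary.
Grayscale images use ordinary bilinear interpolation.

After alignment, c is the vertical extent (max row − min row) of the union
of both masks, a continuous-length convention consistent with the
Euclidean distances used for a and b.

## TDA: canal midlines and radii partition

**Midlines.**  For every image row intersecting the apical mask,
background runs flanked on both sides by apical pixels are canal cross
sections; the run midpoint is, by construction, equidistant to the left
and right flank within that row.  Midpoints are linked across rows into
polylines by nearest column (at most 5 px of lateral jump, at most 2
missing rows).  Three robustness rules, all fixed at design time, decide
which polylines are canals:

1. a polyline must span at least 4 rows (single-row gap artifacts near
   eroded tips are not canals);
2. a gap can only continue a polyline if its width is compatible with the
   polyline's current width (|Δw| ≤ max(4 px, 60 %) — canal width varies
   slowly row to row, which stops bridge artifacts from capturing a canal);
3. among polylines that reach the apical rows (within 30 % of the band
   height of the lowest row — the two roots rarely end on the same row),
   preference goes to gaps that *narrow* apically: an open apex converges
   toward its tip, whereas the inter-radicular space between the roots
   widens.  Terminal depth only breaks ties.

If fewer than two canal midlines survive, the tooth is reported as
`ClosedApexError` — the same exclusion the measurement protocol applies to
radiographs without two visible apices.  Small connected components
(< 5 px) are removed from the apical mask beforehand; isolated specks from
segmentation noise would otherwise split the row gaps.

**Radii partition.**  From every midline point, rays at 1° steps (march
step 0.5 px) label the first apical pixel they hit.  First-hit boundary
pixels form the *inner* (pulp–dentine) interface; the remaining boundary
is *outer* (tooth–environment).  The apex flank on each side of a canal is
the most apical inner pixel, with near-ties (within 2 rows, resampling
jitter) broken toward the pixel nearest the canal terminus, and a
half-pixel correction toward the canal because the true interface lies
between the wall pixel's center and the background.  The strict rule
"inner pixel 8-adjacent to an outer pixel" was tried first and abandoned:
when resampling or segmentation error erodes the tip row, the outer set
vanishes locally and the strict rule walks the extremity outward along the
bottom face, biasing a and b upward by 1–3 px.  a (mesial) and b (distal)
are the Euclidean distances between each canal's two flank landmarks.

A note on exactness: for a discrete annulus, up to 8 diagonal corner
pixels of the inner ring are geometrically occluded from the center —
verified with continuous ray tracing — so no angular refinement makes the
first-hit set equal the full ring.  The partition's contract is therefore
checked against an independent ray-cast oracle at the algorithm's own
angular resolution plus ring-containment properties.

## TDA-DL: skeleton end points and coronal limit points

The apical band is skeletonized (medial axis), spurs shorter than 5 px are
pruned, and the band's inverted-U centerline is the shortest skeleton path
between two end points, chosen per side of the band's median column as the
skeleton node *geodesically farthest* from the band's top center.
Descending branches accumulate geodesic distance, so this lands on the
outermost wall tip; it remains well-defined when skeletonization retracts
a branch unevenly or closes it into a loop (cases where "the most apical
tip" simply does not exist).  Each end is then refined along its branch
direction — a principal-component fit of the terminal nodes, truncated at
the first junction so bridge nodes cannot tilt it — out to the wall end
minus the local medial radius, compensating the variable tip retraction of
discrete skeletons.  Three interior control points at arc-length quartiles
are reported for overlays only.  A mask whose skeleton does not descend
below 1.5× its own maximal thickness is rejected as not band-like (a blob
has a stubby skeleton; a band's skeleton spans its length).

The coronal limit points are the lowest coronal pixels strictly left and
right of the vertical line through the barycenters, ties broken toward the
line.  a and b are the coronal-to-apical limit-point distances per side;
c is shared with TDA.  The construction measures at the apical foramen
while an expert reads the width at the apical constriction, so TDA-DL
systematically overestimates a and b; the decision threshold is rarely
affected because both scores move together.

The skeleton step accepts any backend implementing
`apical mask → 5 ordered (row, col) control points`, so a trained
centerline model can replace the deterministic default without touching
the downstream geometry.

## Evaluation statistics

IoU = TP / (TP + FN + FP) per region (coronal, apical, overall = union),
with mIoU the unweighted per-image mean; two empty masks score IoU 1 with
a flag.  Confusion maps follow the green/orange/red convention for
TP/FP/FN.  Score comparisons use MAE ± sample SD (n−1), Pearson r with the
t-transform p (n−2 df), and the paired two-sided t-test (n−1 df), both via
scipy.  McNemar's test on paired minor/adult decisions uses the exact
two-sided binomial p below 25 discordant pairs and the chi-square statistic
(n01−n10)²/(n01+n10) without continuity correction above (statsmodels
backend); the switch point is a standard choice for samples of this size.
The test suite verifies all three against independent closed-form /
numerical-integration oracles to 10⁻⁶.

## The phantom model

No radiographs ship with the package, so every stage is verified on
stylized phantoms with analytic ground truth.  A phantom tooth is built
from explicit polygons in continuous coordinates:

* **coronal region** — an elliptical crown cap continued by two root-body
  prongs; the two lowest coronal points ("cusps") sit on each canal's
  inner flank, one cervical-gap pixel above the apical band.  This mimics
  annotation practice where the coronal mask covers all mineralized tissue
  down to the open-apex region and the two masks meet at a thin drawn
  boundary;
* **apical region** — a short band (12 px) of four trapezoidal walls, two
  per root, converging from a 3 px taper to tips whose openings are
  exactly a and b pixels wide, joined by a 4 px bridge; canals are open
  from the band to the apices.

The whole scene, including every landmark (wall-tip pairs, cusps, top and
bottom extremes, outer-wall medial tips), is rotated analytically before
rasterization, so ground truth is exact at any rotation; rasterization is
boundary-inclusive point-in-polygon at pixel centers.  Rendering is two
gray levels plus Gaussian noise (σ = 6) — deliberately schematic, because
the measurement contract is geometric, not photometric.

Default cohort conditions: a, b ~ U[6, 20] px, c ~ U[120, 200] px,
rotation ~ U[−20°, 20°], crown width ~ U[100, 130] px, n = 100.  The
geometry of the apical band was chosen by an analytic design computation:
with the cusp on the canal's inner flank, the TDA-DL limit-point gap is
g(x) = √((x + t/2)² + v²) for an apex of width x, with v the
cusp-to-medial-tip vertical offset (band + gap − t/2 = 10.5 px by
default).  This keeps g width-scaled with a modest systematic
overestimate (≈ 6 px per apex) and makes the two methods' scores strongly
concordant at truth level (r ≈ 0.96 over the default cohort ranges) —
the regime the measurement literature reports.  Larger v (a longer band or
gap) degrades the concordance ceiling rapidly; v is a phantom-design
quantity, not a tunable of the measurement algorithms.

`degrade_mask` simulates segmentation error as a smooth boundary
displacement: the signed distance to the mask boundary is thresholded
against a spatially correlated Gaussian field (σ = 6 px), tanh-bounded so
the local shift never exceeds 3·severity px and scaled by local structure
thickness — a segmentation net misplaces the contour of a large region by
more pixels than a thin wall can absorb — plus sparse speckle near the
region.  Calibrated to a mean overall IoU of 0.90, this yields apical IoU
≈ 0.77, reproducing the published per-region quality pattern (coronal
easy, apical hard).  An earlier disk-punch model at the same overall IoU
destroyed the thin walls outright (apical IoU ≈ 0.5) and was discarded as
an unrealistic error mode.

**What passing phantom tests does and does not show.**  The phantoms
exercise geometry (alignment, canal detection, landmark placement,
invariances) with exact ground truth, but they are not anatomically
realistic: real third molars have curved roots, variable canal
morphology, overlapping anatomy, and graded radiodensity.  Passing the
phantom battery demonstrates the post-segmentation measurement is correct
and robust to rotation, mirroring, scale, and boundary-quality
segmentation error — not that any segmentation model is accurate on
clinical images.

## Verification battery (scripts/acceptance.py)

The script recomputes, from scratch at a given seed: exact agreement of
IoU with brute-force set arithmetic on 1,000 random 32×32 mask pairs; the
shifted-square confusion cell (tp=1, fp=3, fn=3, IoU=1/7); the worst
statistic/p deviation from the independent oracles over 100 random
samples; the worst midline flank imbalance over 50 phantoms; a+b recovery
within ±4 px, c within ±3 px and |ΔI3M| ≤ 0.03 rates on the 100-phantom
cohort; max I3M shift under ±30° pre-rotation; the a+b change under
mirroring; the I3M change under 1.5× rescaling; decision agreement on
clean and on degraded masks (severity bisected to overall IoU ≈ 0.9); and
the Pearson correlation between the two methods' scores.  Problem sizes
match the cohort conditions above; the full run takes ~30 s on one CPU.

## Known limitations

* Two-rooted, two-apex teeth only; more canals (or maxillary molars) are
  out of contract and surface as errors rather than wrong numbers.
* The canal detector assumes near-vertical canals after alignment; a
  pathology that bends a canal past ~45° would break row-scan linkage.
* The TDA-DL default backend is deterministic skeletonization, not the
  learned centerline model of the original procedure; the backend
  interface exists precisely so one can be plugged in.
* Population-specific recalibration of the 0.08 threshold, probabilistic
  age posteriors, and automated tooth detection/cropping are out of scope.
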