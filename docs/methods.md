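# Methods

## Problem and model

A nadir survey photograph of a nodule field is modelled as two spatially
coherent grey-value classes: dark, compact, mostly convex objects (class
ω0) embedded in a brighter sediment background (ω1), degraded by an
illumination cone, sensor noise, marine-snow speckles and partial
sediment cover of the objects.  The pipeline makes exactly two
assumptions: (i) objects are darker than their background after colour
correction, and (ii) objects are compact and roughly elliptical.  No
training data and no feature computation are involved; the only
parameters are θγ (threshold selection) and θr (minimum object radius in
px).

## Phase 1: co-occurrence threshold selection

The preprocessing order is fixed: 3×3 median (sensor-noise and impulse
removal) → bicubic rescale by √(A_i/A*) to a common px/cm (A_i = image
footprint, A* = survey median footprint; the square root converts the
area ratio into the linear factor that actually equalises px/cm) → 3×3
Gaussian (σ = 0.8 px) → illumination correction → BT.601 grayscale.
All borders use edge replication; every stage is deterministic.

The binarisation threshold for an image is selected from its symmetric
grey-level co-occurrence matrix over the four forward Moore offsets
(E, S, SE, SW — each unordered 8-neighbour pair counted once, then
symmetrised).  The compactness γ(t) is the fraction of pairs with both
members on the same side of t; γ(255) = 1 identically.  The forward
difference γ′ peaks at p where the background mass is resolved, and the
threshold is the highest b < p with γ′(b) < γ′(p)·θγ.  If no such b
exists the image is skipped with a warning and NaN statistics — a
threshold is never guessed.  A 5-tap moving-average smoothing of γ′ is
available (`derivative_smoothing`) but off by default; the raw
difference is what the selection rule sees.

### Illumination / colour correction

The correction approximates data-driven flat-fielding in three steps per
channel: estimate a smooth brightness field, subtract it and re-centre
at mid-grey, optionally equalise the histogram.  Three details matter
and are deliberate design choices of this package:

* **Robust field estimate.**  A plain Gaussian low-pass of the image is
  pulled down wherever dark objects cluster, re-modulating the corrected
  background by several grey levels.  The field is therefore estimated
  in two passes: a grey closing (separable square structuring element,
  half-width equal to the Gaussian scale — a rolling-ball-style rank
  filter that fills dark objects) gives a provisional field; a
  normalised-convolution Gaussian over inlier pixels
  (|deviation| ≤ max(8, 3·MAD)) gives the final one, free of the rank
  filter's envelope bias.  The field scale is
  `lowpass_fraction · min(H, W)` px (default 0.02); as with any
  rolling-ball background, it must exceed the largest object diameter,
  and `lowpass_fraction` should be raised for small frames or very
  large objects.
* **Border handling.**  Even-reflection or edge-clamped smoothing
  flattens the illumination ramp at the image border, leaving an
  under-corrected dark rim that leaks into the foreground mask as
  border-hugging false objects.  All field smoothing therefore runs on
  odd-reflection (antisymmetric) padding, which preserves linear trends
  through the border.
* **Half-integer re-centring.**  The corrected image is re-centred at
  126.5 rather than 127.  On well-corrected imagery the background is
  quantisation-limited (sub-grey-level residual spread): centred on an
  integer it piles ~85 % of its mass onto a single grey level with a
  heavy one-level lower tail below the selected threshold; centred on a
  rounding boundary it splits evenly over two levels and the
  below-threshold leakage drops by an order of magnitude.  For
  backgrounds wider than a few levels the offset is immaterial.
* **Equalisation off by default.**  Global histogram equalisation
  stretches grey levels in rank space, amplifying background pixel-pair
  differences around the sediment mode and destroying the compactness
  structure the threshold selection needs; the cross-image brightness
  consistency it would provide is already achieved by the common
  re-centring.  It remains available (`equalize=True`) for visual
  normalisation; a single-bin histogram maps to itself.

## Phase 2: delineation

Exact Euclidean distance transform of the mask (an all-foreground mask
measures distance to the image border); local maxima under the
≥-all-8-neighbours rule, one representative (topmost-leftmost) per
plateau component; greedy suppression keeping the highest peak within a
5·θr radius (Euclidean; ties by height broken row-major).  Candidates
whose distance-map height — their blob's inscribed radius at that point
— is below θr are dropped before suppression: a centre narrower than the
minimum nodule radius cannot belong to a nodule, and this removes thin,
straggly false-foreground structures that can exceed the π·θr² area
cut-off while never being as wide as a real object.

Pixels are assigned to peaks by marker-controlled watershed on the
negated distance map (8-connectivity), the standard realisation of
bottleneck splitting with guaranteed one-region-per-marker termination.
Blobs containing no retained peak stay unlabeled and vanish.  Blobs
smaller than π·θr² px are visited in ascending area order and fused with
their largest neighbour whose boundary-to-boundary distance is < 2·θr
px, or discarded when none exists; the pass repeats until stable.
Surviving blobs are delineated by the convex hull of their pixel
coordinates (closing gaps from sediment cover), and each hull is fitted
with a direct least-squares ellipse (moment-based fallback for 3–4-point
hulls; hulls thinner than half a pixel are rejected).  Sizes are
π·a·b from the fitted ellipse converted through the px/cm resolution —
not the raw pixel count — matching how the delineations are defined.

## Statistics and gridding

Φᴺ = N/A; Φᶜ at image level uses the union of the fitted ellipses
clipped to the frame (so overlapping fits cannot exceed 100 %), while
per-object sizes stay unclipped.  The accumulation sizes Φˢ_α sort sizes
ascending and return s[k] for the largest k whose cumulative sum stays
strictly below α·Σs (s[0] when even the first size fails).  Trask
sorting and skewness follow from the 25/50/75 % values.  Gridding
anchors a square-cell grid at the min-lat/min-lon corner of the survey
bounding box under a local equirectangular metric, assigns each nodule
to the cell containing its centroid (conserving counts), computes cell
statistics over the cell area, and pools overlapping images with max
(default) or mean.  Maps export as long-format CSV plus an ESRI ASCII
grid raster (plain text, NaN as NODATA).

## Synthetic scenes and what the tests show

`SceneSpec` defaults describe a low-altitude survey: 1024² px at
5 px/cm (≈1 m altitude at a 90° field of view, 4.19 m² footprint),
36 objects with lognormal areas (median 48.6 cm², log-σ 0.6, the
published median size for abyssal Pacific nodule fields; equivalent
radius ≈3.9 cm ≈ 20 px), axis ratios uniform in [1, 2], ≈5 % coverage,
20 % of objects planted touching a neighbour, object/background grey
60/150, smooth ±2.5-level sediment-albedo texture at a ~512 px (metre)
scale, a 30 % multiplicative illumination cone, 100 bright single-pixel
speckles per Mpx, 5 % single-pixel sediment dusting of each object, and
additive sensor noise σ = 0.5 grey levels.  Objects are rasterised with
4× supersampled anti-aliasing so the stored truth area is the analytic
π·a·b.  The same spec and seed reproduce scenes byte-identically.

Tool defaults θγ = 0.10 and θr = 4 px (0.8 cm at 5 px/cm, below the
smallest planted nodule radius of ≈2 cm) were fixed once for these
conditions using the single-image preview workflow; on other imagery
both parameters are meant to be explored per dataset with
`comonod preview`.

The recovery suite (ten seeded scenes) checks aggregate object count
within ±10 %, coverage within ±1.5 percentage points and median
accumulation size Φˢ_0.5 within ±15 % of ground truth, plus
non-decreasing recovery error as sensor noise doubles.  What passing
does **not** show: performance on real imagery with biofouling, fauna,
strong scattering, non-elliptical nodules, or backgrounds whose
post-correction residual exceeds a few grey levels.

## Known limitations

* **Operating envelope of the compactness criterion.**  The selection
  rule stops at the first quiet point of γ′ below the peak, which lies
  at the lower flank of the background mode.  The mask therefore always
  includes the background's lowest occupied grey level(s); the method
  only yields clean masks when the corrected background is
  quantisation-limited (residual spread ≲1–2 grey levels).  Strong
  sensor noise or uncorrected texture moves the compactness minimum to
  the background mode itself and the threshold floods the mask — this is
  the documented failure mode, visible in the noise-degradation test.
* **Soft-edge size bias.**  Because the threshold sits near the
  background edge, the ~1 px soft edge (anti-aliasing + the mandated 3×3
  Gaussian) joins each object's mask, adding roughly one pixel of
  radius.  At 20 px median radius this is a ~+10 % area bias (within the
  recovery tolerances); at a few px per object radius it inflates areas
  by >50 %, so surveys should be imaged or rescaled such that the
  minimum object radius is ≳10 px.
* Coverage leakage of a fraction of a percent of background pixels at
  the threshold level is irreducible; it is cleaned by the θr rules and
  contributes the remaining ~+0.5 pp coverage bias.
* The grid's equirectangular metric ignores Earth curvature (negligible
  below ~km extents); nodules are assigned to cells whole, by centroid.
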