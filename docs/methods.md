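# Methods

This note records the model, the numerical choices and the validation
design behind `octangle`, at the level of detail a maintainer or reviewer
needs to judge what the results do and do not show.

## Coordinate and calibration conventions

All coordinates are 0-based `(row, col)` with row 0 at the top (anterior)
and rows increasing posteriorly. Calibration is a single isotropic
μm/pixel scale; the reference device frames are 256 × 1024 px over
8 mm × 16 mm, quoted as 31.3 μm/pixel. The 8/256 mm axis matches that
figure exactly (31.25) while 16/1024 mm would give 15.6 — whether the
device resamples to isotropic pixels is not documented, so the package
treats the scale as isotropic and, when a DICOM header carries anisotropic
pixel spacing, warns and uses the row spacing. Intensities are normalized
to [0, 1] by dtype range on input; the per-column thresholding makes the
chain insensitive to global brightness.

Unit conversion rounds half away from zero by default (500 μm at
31.3 μm/px → 16 px; 750 μm → 24 px), with `ceil`/`floor` variants. RAW
input is headerless, row-major, little-endian, top row first; dimensions,
bit depth and scale must be supplied.

## Segmentation chain

1. **Median filter**, 3×3 (5×5 optional), edge replication
   (`scipy.ndimage.median_filter`, `mode="nearest"`).
2. **Per-column Otsu**: each column is quantized to 256 levels and split
   at the threshold maximizing between-class variance. Ties take the
   lowest threshold (determinism); zero-variance columns binarize to
   background so air columns never create foreground. The vectorized
   implementation is tested against an exhaustive 256-candidate oracle
   and against `skimage.filters.threshold_otsu` on random histograms.
3. **Hole filling**: background components not 4-connected to the border
   (`scipy.ndimage.binary_fill_holes`), removing speckle holes inside the
   tissue bands without touching the chamber, which always reaches the
   border.
4. **Scleral boundary**: per column, the first anterior→posterior
   transition of the largest foreground component (smaller specular
   components above the cornea are thereby ignored), approximated by a
   degree-4 least-squares polynomial fit with columns scaled to [−1, 1]
   for conditioning and coefficients reported in original coordinates.
5. **Wedge tracing**: per column, the widest dark gap inside the tissue
   component gives a cornea-inner-edge point and an anterior-iris point.
   Contiguous gap-column blocks separated by at most 8 closed columns are
   merged — a focal near-touch of the contours (a narrowed angle) closes
   the rasterized gap locally and must not split the wedge. The block is
   oriented so the apex (smaller gap) is at the closed end.
6. **Apex**: the wedge's deepest point. The k-cosine curvature maximum
   (window 5, ties to the smallest column) is searched in a ±12-vertex
   neighborhood of the cornea→iris junction of the chamber-boundary
   polyline — restricting the search there keeps a sharp focal iris bump
   from outcompeting the wedge tip. Because rasterization merges the tip
   over roughly gap/tan(θ) columns, the curvature estimate is biased
   outward for narrow angles; the apex is therefore refined to the
   intersection of line fits through the first eight observed vertices of
   each contour (falling back to the curvature point when the fit is
   degenerate or the intersection moves more than 15 px). The contours
   are prepended with a Bresenham bridge from the refined apex so both
   remain 8-connected pixel polylines with the apex as first vertex; the
   bridged arc length is recorded (`bridge_px`) because those vertices
   are interpolated, not observed.
7. **Region of interest**: the end-to-end pipeline traces contours up to
   64 px (~2 mm) of arc from the recess by default. Iris visibility
   beyond ~2.5 mm of the angle does not occur anatomically — lengths
   above that bound are tracing failures by definition — so the ROI
   keeps the iris-length QC screen meaningful; `max_arc_px=None`
   traces the whole visible wedge.
8. **Scleral spur**: an explicit spur is the first-class pathway (the
   spur is invisible in roughly a fifth of clinical scans, and no
   published automatic rule exists). The built-in heuristic refits the
   quartic to the scleral boundary restricted to the cornea-contour span
   and takes the column with the maximum anterior residual in the
   apex-side half (the spur anatomically neighbors the recess and anchors
   the windows that extend from it); residual maxima under 1.25 px raise
   an anchoring error rather than guessing. A supplied spur is snapped to
   the nearest contour vertex.

A fully closed angle (no dark gap anywhere) is returned with a `closed`
flag and coinciding contours instead of failing; all distance metrics then
report 0.

## Metric definitions and numerical choices

- **Window**: the w ∈ {500, 750} μm cornea window extends from the spur
  *toward the recess* and contains the vertices within the pixel-count
  equivalent of w (16 px at 31.3 μm/px) strictly beyond the spur. A spur
  closer than w to the apex truncates the window with a warning.
- **AOM**: exact pairwise minimum between the windowed cornea vertices and
  *all* iris vertices (`scipy.spatial.distance.cdist` on squared
  distances); the achieving pair is recorded, ties broken
  lexicographically by (cornea, iris) vertex for determinism. **AOM2**
  swaps the roles, windowing the iris over the arc span (from the apex)
  that the cornea window covers.
- **AOD**: the cornea point at arc w from the spur is snapped to the
  nearest contour vertex inside the pixel-count window, so the AOD point
  belongs to the AOM search set and the definitional ordering AOM ≤ AOD
  holds exactly, including on sub-pixel analytic contours. The
  perpendicular to the local tangent (central difference over ±2 px of
  arc) is cast toward the iris; the value is the distance to the first
  polyline crossing, falling back to the nearest iris point (flagged)
  when no crossing exists.
- **TIA**: total-least-squares (PCA) lines with outward-oriented
  directions, fitted over the observed vertices between the apex bridge
  and the spur's arc distance (or [0, w] without a spur); the angle of the
  two directions lies in [0, 180) and parallel contours give 0°. Excluding
  the interpolated bridge and fitting out to the spur keeps the
  rasterization sawtooth from tilting short-window fits; worst-case
  segmented recovery error across 8–45° wedges is below 0.7°.
- **TISA**: shoelace area of the ring spur → cornea → C → AOD segment → I
  → iris → F → spur, where F is the foot of the perpendicular from the
  spur onto the iris; here C is the *exact* interpolated arc position
  (vertex snapping would cost up to ~4% area). Validity is checked with
  shapely. One self-intersection is expected by construction: for wide
  angles (θ with spur·cos²θ < spur − w, ≈ 40° at the defaults) the AOD
  foot lands beyond F and the signed shoelace — which subtracts the
  overshoot lobe — is the area the four boundary curves enclose; any
  other self-intersection raises a measurement error with shapely's
  diagnostics.
- **AOS**: both contours resampled to equal vertex counts by arc length
  from the apex; the sequence is the per-index distance in μm. The
  alphabet encoder classifies successive differences against a flat
  tolerance (default half a pixel-equivalent) into increasing runs (`/`),
  flat runs (`_`) and interior extrema. The printed convention assigns
  `^` to a local minimum and `v` to a local maximum; an
  `invert_extrema` switch swaps them for readers who expect the
  pictographic convention.

## QC filters

Iris contours shorter than 16 px (one 500 μm window) cannot support the
windowed metrics and are excluded as ineligible — not algorithm errors;
contours longer than 70 px (~2.5 mm; the upper figure of the quoted
70–80 px range, configurable) do not occur anatomically and flag tracing
failures. Δ = AOD − AOM partitions at 22 px into definitional
undershoot versus algorithm error. Summary percentages round half up to
one decimal.

## Phantoms: what they emulate and what they do not

A phantom is two bright bands (intensity 0.8 on 0.05 background, 11 px
thick) leaving a common apex: the cornea inclined upward at θ_c, the iris
downward at θ_i, wedge angle θ_c + θ_i (default split: iris takes
min(10°, θ/4), keeping steep corneas inside a 256-row frame). Options add
quadratic curvature, a Gaussian focal anterior iris bump (position, depth,
width in μm), a scleral-spur protrusion on the outer boundary, additive
Gaussian noise and multiplicative speckle, all under a single seeded
generator. Ground truth carries per-column sub-pixel contours, the spur
at a configured geodesic distance from the apex, the true angle, and the
minimum iris–cornea separation inside the window evaluated on a 0.05 px
sampling of the exact profiles (accurate to ≪0.1 μm and independent of
the measurement pipeline).

The spur sits at 1200 μm of corneal arc from the apex, so the 500 μm
window spans arcs 700–1200 μm from the recess. At that placement the
clinical thresholds cohere on an ideal wedge: AOD = 700·tanθ μm crosses
190 μm at θ ≈ 15.2°, consistent with the TIA < 15° criterion.

`sample_population` draws stratified cohorts with an exact narrow count:
narrow phantoms are small wedges (6–13°) or open-looking wedges (22–30°)
with a focal bump bringing the window minimum below 190 μm — the
morphology that point measurements miss; open phantoms are 25–45° with
minima comfortably above. Labels come from the analytic truth (angle
< 15° or separation < 190 μm), never from the pipeline being tested.

Phantoms deliberately omit realistic OCT speckle statistics, the ciliary
body, Schwalbe's line, iris curvature variability and device artifacts.
Passing tests therefore demonstrate the correctness of the geometry,
segmentation machinery and classification plumbing under controlled
conditions — not clinical accuracy. In particular, the in-silico
narrow-angle AUC of ~1.0 reflects the clean synthetic separation; the
clinically reported separability of this family of methods (AUC in the
high 0.7s to high 0.8s on large labelled cohorts) cannot be reproduced
without that data and is cited as context only.

## Validation design and problem sizes

Each kernel has an independent oracle: sliding-window medians and Otsu
thresholds by exhaustive search, hole filling by border flood fill,
minimum distances by O(n·m) double loops, quartic fits by polynomial
interpolation of their own graphs, metrics by trigonometric closed forms
on analytic wedges (parametrized by the *realized* spur arc, since the
spur snaps to a contour vertex), ROC by the rank statistic
(`sklearn.roc_auc_score`) and permutation expectation. Segmentation
recovery is checked on 50-phantom populations (RMS ≤ 1 px noise-free,
≤ 2 px at σ = 0.05); the end-to-end classification on a 400-phantom
population at σ = 0.02 — sizes chosen so the whole suite and the
acceptance script each complete in well under a minute while the
recovery statistics are stable across seeds. Determinism is enforced
end to end: identical inputs and seeds produce byte-identical CLI
artifacts.

## Known limitations

- The scleral-spur heuristic is a stand-in validated only on phantoms
  with rendered protrusions; on real scans an explicit spur (or a
  trained detector) is the realistic pathway.
- The apex refinement assumes locally straight contours near the recess;
  strong curvature within ~8 px of the apex would bias it.
- Contours from segmentation are integer pixel polylines; sub-pixel edge
  refinement would reduce the residual TIA/AOD quantization error but is
  deliberately out of scope.
- The wedge tracer assumes one anterior chamber wedge opening laterally
  (either direction); unusual geometries with multiple dark wedges inside
  the tissue component are resolved by size, which may mistrace
  pathologies the phantom family does not model.
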