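# Methods

This note records the models, conventions and design decisions behind
`histocyto`, in the order data flows through the package.

## Input model and units

A *cell of interest* (COI) is one segmented cell, represented jointly by a
row in the results table and a polygon contour in `roi.zip`, keyed by a
shared positive integer id. Intensities are per-channel means over the
membrane ring in arbitrary units bounded by [0, 255]; 16-bit image data are
mapped linearly by 255/65535 from the full dynamic range (not data min–max),
so values stay comparable across images. Coordinates are 0-based pixels,
origin top-left, x = column, y = row; slices and channels are 1-based.
Column names follow Fiji export conventions and are matched
case-insensitively with synonyms (`XM`/`X`, `Circ.`/`circularity`, an
unnamed leading index column as the id, ...) because segmentation macros do
not agree on headers.

## ImageJ `.roi` codec

Contours are stored in the ImageJ ROI binary format: a 64-byte big-endian
header (`Iout` magic, version, type byte, signed 16-bit bounding box, vertex
count, stack position at offset 56) followed by x- then y-offsets relative
to the bounding-box corner as signed 16-bit integers. Only polygon-like
types (polygon 0, freehand 7, traced 8) are accepted; the slice is read from
the position field, falling back to the header2 z-position, else 1. Entries
are named by zero-padded id (`0042.roi`); on read, a single integer in an
entry name is the id, and Fiji-style multi-number auto-names fall back to
entry order with a warning. Archives are written uncompressed with fixed
timestamps so identical inputs produce identical bytes. Polygons whose
relative extent exceeds 32767 px cannot be represented and raise an
overflow error rather than wrapping.

## Resize rule and geometry rescaling

Images whose longest dimension exceeds 1024 px are resized proportionally on
load so the longest dimension is exactly 1024 (2048×1536 → 1024×768), with
target dimensions rounded half-up. Resampling is area-averaging
(anti-aliased), chosen because it preserves intensity statistics better than
nearest-neighbour; loading an already-small image leaves pixels untouched.
`rescale_geometry` multiplies vertices and centroid columns by the scale and
areas by its square, returning new objects so original-coordinate data stay
available for export. Ambiguous multi-page TIFF layouts default to
slice-major page order (channels cycle fastest), switchable per call.

## Measurement stage

Given a labeled nucleus volume (0 background, label k = COI k):

- **Central slice** — per label, the slice maximizing the per-slice pixel
  count; ties break to the lowest slice index. Reversing the z-axis
  therefore maps slice s → n+1−s up to the tie-break.
- **Membrane ring** — `ring = dilate(nucleus, inner_margin + thickness) ∖
  dilate(nucleus, inner_margin)` with disk structuring elements, restricted
  to the cell's *territory*: every pixel belongs to the nucleus nearest by
  Euclidean distance transform, so rings of adjacent cells never share
  pixels and no signal is double-counted. Defaults `inner_margin=1`,
  `thickness=3` px place a 3-px ring one pixel off the nucleus boundary —
  a pragmatic choice for nuclei of roughly 3–10 px radius at typical
  confocal sampling; both are per-call parameters. A ring emptied by
  crowding triggers a warning and NaN intensities rather than a silent 0.
- **Outer contour** — traced from the outer dilation at the 0.5 level,
  rounded to integer pixels with consecutive duplicates removed; in the rare
  case rounding pinches the contour into a self-intersection, the convex
  hull of the mask is used instead.
- **Morphology** — computed from the outer polygon (the same object saved to
  `roi.zip`): shoelace area, circularity 4πA/P² clamped to ≤ 1, solidity
  A/A_hull clamped to ≤ 1. Note that mean intensity within the ring is a
  *mean*, not a median or integrated density; this is the single summary the
  table stores.

## Spatial analysis

DBSCAN runs on the 2D centroids of the central slices (z is ignored —
within-section distances are what tissue-region membership means here).
The implementation is the textbook algorithm over KD-tree neighbourhoods:
core points have ≥ `min_pts` neighbours within `eps` including themselves;
clusters are reachability-connected cores plus borders; border points
reachable from two clusters go to the first cluster discovered, made
deterministic by processing ids in ascending order. Defaults `eps=50` px,
`min_pts=5` are arbitrary and should be tuned to the tissue; the region flag
is written to the `ROI_DBSCAN` column as 0/1. The interaction criterion is
dilation-overlap: a cell interacts (flag 1) iff its outer polygon, buffered
by `contact_dist` px, covers at least one partner-mask pixel centre on the
cell's own slice — monotone in `contact_dist` by construction. The partner
mask is a per-slice threshold of a chosen channel (threshold is a parameter;
other mask sources can be passed directly). Points exactly on a drawn
region-polygon edge count as inside, matching what users expect when
circling cells.

## Gating conventions

All intervals are closed and a value exactly at a threshold belongs to the
upper/right/second class — one convention applied to filters, rectangles,
quadrants and shape rules alike, so compositions never leak or double-count
boundary cells. Quadrants partition the filtered set by construction
(LL: x<x_t ∧ y<y_t, LR: x≥x_t ∧ y<y_t, UL, UR). Lasso membership is
boundary-inclusive point-in-polygon. Multiple-selection mode is set union
with ascending-id output. Gate files are JSON with a `schema_version` field;
files from a newer schema raise an explicit error instead of misparsing.
Geometry is stored in data units so gates transfer across images of the same
staining panel. Statistics export as two CSVs (population summary, per-cell
members) to stay machine-parseable. Annotation edits apply in order,
conflicts resolve last-wins with a warning, and the audit log records old
values so any edit can be reverted exactly.

## Rendering

Overlays stroke member contours with midpoint-line rasterization between
consecutive vertices (closed), dilated by a disk for thickness > 1, over the
composed channel image (channels map to a fixed red/green/blue/magenta/
yellow/cyan cycle, summed, scaled by gain, clipped to [0, 255]). Only
contours whose slice equals the displayed slice are drawn. Id labels use a
built-in 3×5 bitmap digit font at a fixed offset right of the contour's
bounding box; overlapping labels are logged, not deconflicted — determinism
is preferred over aesthetics, and the tests rely on byte-identical output.
Crops replicate pixels by an integer factor (magnification is rounded), so a
crop at magnification 1 and margin 0 is exactly the composed bounding box.

## Synthetic scene generator

The generator emulates the structure of a stimulated lymphoid-tissue
acquisition, not its optics. Nuclei are spheres with integer radii at
integer centres; because a lattice point at distance exactly r from the
centre always exists, the central slice's cross-section is strictly the
largest and ground truth is unambiguous. Membranes are painted as shells
wide enough to cover the entire measurement ring, so with zero noise the
measured ring mean equals the planted value exactly — the identity the
measurement tests assert. Phagocyte contacts are disks painted on a
dedicated channel overlapping the target cell's ring zone; cell spacing
(34 px minimum between centres) is chosen so a blob can never reach another
cell's dilated contour, making planted contact flags exactly recoverable at
`contact_dist=2`.

The default preset mirrors the use-case scale: 176 cells (80 T-like with
LT ≈ N(180, 10), 70 B-like with LB ≈ N(180, 10), 26 uncharacterized at
(30, 30)), 6 channels, 12 slices, pixel noise SD 5, in a 1024×1024 image —
the largest size that loads without resizing, needed to give the planted
density structure room. The dense region is a disk of radius 300 px holding
65% of the cells at the minimum spacing; the remaining cells are placed
outside the disk plus an `eps` buffer and kept mutually farther than `eps`
apart, so they are DBSCAN noise by construction. The DBSCAN parameters used
on generated scenes follow the construction: `eps` = 2× the minimum spacing
(68 px), `min_pts` = 4; at the planted in-disk density each interior cell
expects ≈ 6–7 neighbours within `eps`, so only occasional disk-edge cells
can fall out of the cluster (observed 0–2 per scene across seeds). Placement
is rejection sampling with up to 1000 attempts per cell; infeasible packings
raise an error suggesting smaller counts. One random stream seeded from
`SceneSpec.seed` is consumed in a fixed order (populations, cluster
membership, radii, placement, axial positions, intensities, contacts,
noise), and all file writers use fixed timestamps, so identical seeds give
byte-identical bundles.

What the generator does **not** emulate: point-spread blur, chromatic
bleed-through, autofluorescence, irregular nucleus shapes, z-anisotropy and
segmentation errors. Tests passing on these scenes therefore demonstrate the
correctness of the measurement/gating/spatial machinery on well-defined
geometry, not robustness to real acquisition artefacts — on real data the
limiting factor is the upstream segmentation, which this package
deliberately takes as input.

## Problem sizes and numerical notes

The test suite and the acceptance script run everything at the scales above:
format round trips over 1000 random polygons and a few hundred random
tables, oracle comparisons at up to 1000 rows (gating) and 200 points
(DBSCAN, where the brute-force closure oracle is O(n²)), and one full
176-cell bundle per run. A quadrant split at the midpoint of a two-axis
mixture recovers (1 − Φ(−s/2))² of memberships at per-axis separation s SD
— ≈ 95.4% at 4 SD, ≥ 99% from ≈ 5.2 SD — which is why the default preset
separates its populations by 15 SD. Degenerate inputs are contracts, not
crashes: empty tables, empty ROI archives and zero-cell scenes round-trip;
empty rings yield NaN; empty gates keep their zero rows in statistics.

## Known limitations

- Only polygon-like ROI types are decoded; composite, oval, line and point
  ROIs are rejected by design.
- Pyramidal/tiled TIFFs are out of scope; stacks are loaded whole.
- DBSCAN membership is binary; neighbourhood statistics beyond membership
  (cluster composition, contact networks) are not computed.
- The interaction criterion is dilation-overlap with a mask; shared boundary
  length or 3D contact area are not measured.
- Gating is single-level (filter → gates → optional union); hierarchical
  gating trees are not supported.
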