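# Methods

This note documents the recognition model, the choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
establish about real figures.

## Image model and conventions

All stages operate on numpy arrays in `(row, col)` coordinates, origin
top-left. A `RasterImage` is `uint8 (H, W, 3)`, a `GrayImage` is
`uint8 (H, W)`, a `BinaryImage` is `bool (H, W)` with `True` = foreground
ink. Grayscale conversion uses ITU-R BT.601 weights (0.299, 0.587, 0.114),
rounded to the nearest integer; the choice only nudges thresholding and
any of the common weightings would do. Alpha channels are composited onto
white on load because tree figures sit on light backgrounds; light-on-dark
figures are handled by the `invert` filter before thresholding.

Foreground/background connectivity follows the standard digital-topology
pairing: 8-connectivity for foreground curves, 4-connectivity for
background regions (this is why the `fill` tool floods 4-connected — it
cannot leak diagonally through a line crossing).

## Thresholding

A pixel is foreground iff its intensity is **strictly below** the
threshold. The automatic global threshold maximizes Otsu's between-class
variance by exhaustive scan over all 256 cut points; the objective is
compared as exact integer cross-products
(`(s0*w1 - s1*w0)^2 / (w0*w1)`, cross-multiplied), so ties are broken
deterministically at the lowest cut and the result is bit-identical to a
brute-force per-pixel scan — the test suite verifies exactly that. On a
constant image no cut separates anything and the threshold degenerates to
the constant itself (everything background). The local threshold is
mean-minus-offset over an odd, edge-replicated window, evaluated on
integer window sums for the same reason: a pixel equal to its window mean
is background, with no floating-point edge cases.

## Skeletonization

Thinning is Zhang–Suen (scikit-image's `skeletonize(method="zhang")`),
wrapped to satisfy four contract properties: the skeleton is a subset of
the input foreground, the 8-connected component count is conserved, no
2×2 all-foreground block remains, and the operation is idempotent.
Zhang–Suen alone leaves 2×2 blocks on diagonal staircases, so a cleanup
pass deletes block pixels that are 8-simple (Hilditch crossing number 1).
Two genuinely hard cases remain and are handled explicitly:

* **X-crossings on cycles** — at a crossing of two diagonal lines no block
  pixel is locally simple; if the crossing lies on a cycle, deleting one
  pixel merely opens the loop, which the cleanup accepts after verifying
  the global component count is unchanged.
* **X-crossings off cycles** — here any deletion would sever one arm, so
  the cleanup re-attaches the arm through a neighboring pixel of the
  *pre-thinning* foreground (the subset invariant is relative to the
  parent image, which is exactly what makes this legal).

Thinning and cleanup are iterated to a joint fixpoint (bounded at 25
passes; 2–3 suffice in practice) because the cleanup can expose redundant
corner pixels that the next thinning pass removes — this is what makes
`skeletonize` idempotent as a whole.

## Node detection

On a unit-width skeleton, a masked pixel with exactly one masked neighbor
is a tip; a pixel with ≥ 3 neighbors is a branching candidate. Candidates
are clustered by 8-adjacency and each cluster becomes one inner node at
the cluster centroid **snapped to the nearest cluster pixel** (ties broken
by row, then column) so node positions always lie on the skeleton; an
averaged position could fall off a diagonal junction. Pixels with exactly
two neighbors are path interior and never nodes; isolated pixels are
ignored with a warning (noise, not taxa). The whole cluster — not just the
representative pixel — acts as the node during tracing; otherwise a path
could slip through a junction via a non-representative junction pixel.

## Branch tracing

A branch is the geometrically shortest skeleton path (axial step 1,
diagonal √2) between two nodes whose interior touches no third node.
Node-blocking is essential: without it every pair of tips would be joined
by a path and the result would not be a tree. The search is Dijkstra from
each node over the pixel graph; entering another node's junction cluster
confines the search to that cluster, so paths terminate at the node's
canonical position without crossing the junction. Ties between
equal-length paths are resolved by the fixed neighbor scan order (axial
before diagonal, row before column) and the `(distance, pixel)` heap
order — deterministic, and cheaper than comparing whole pixel sequences,
which is all the determinism contract needs. Node pairs with no node-free
path simply get no branch; missing structure surfaces as diagnostics from
`validate` (disconnection with component memberships, cycles, bad
degrees), which replaces the visual inspection of an interactive session.

In headless runs without a flood seed, the component stage keeps every
skeleton component at least 5 % the size of the largest. A broken tree
then yields a disconnection diagnostic instead of being silently truncated
to its biggest fragment, while specks and detached glyphs are still
dropped. Supplying an explicit seed restores strict single-component
flooding.

## Branch length measurement

*Freeform* mode sums the step lengths of the entire pixel path. In
*rectangular* mode only horizontal extent carries signal, so the path is
segmented into maximal straight runs: per-step 8-way direction codes are
smoothed by a majority vote over a 5-step window (staircase aliasing of a
slightly rotated scan would otherwise shatter a branch into many tiny
runs), and the path splits where the smoothed code changes. A run
contributes its geometric length iff the angle between its interior
endpoints and the horizontal is at most the slope tolerance; the first
and last pixel of a run are trimmed from the angle estimate because they
sit on the elbow or on a junction pixel snapped off the line, which would
bias short runs by several degrees. The default tolerance of 10° keeps
the horizontal portions of figures rotated by a few degrees (the bundled
6° stress battery recognizes ≥ 90 % of them) while excluding anything
near diagonal; skewed rectangular trees can be measured by raising the
tolerance or switching to freeform mode — there is no separate skew mode.

Calibration multiplies pixel lengths by `unit_length / pixel_length` of a
scale bar; overrides replace computed values verbatim and every branch
carries its provenance (`computed` / `scaled` / `manual`) into the report.

## Naming, rooting, serialization

Unnamed tips are numbered 1..n in reading order (top-to-bottom, then
left-to-right); duplicates are suffixed with a warning. The default root
is the leftmost inner node — rectangular phylogenies read left to right
with the root at the left margin. Child order in the Newick output is the
clockwise-from-north angular order of the first pixel step of each child
branch around its parent: geometry-derived, hence stable across runs
(Newick itself has no canonical order). Labels containing
`space ( ) : ; , [ ] '` are single-quoted with internal quotes doubled;
lengths default to 6 significant digits. Round-trip identity against an
independent parser (dendropy) is part of the test contract.

## The fixture renderer

`render_tree` draws a Newick tree with exact ground truth (tip and inner
node coordinates, per-branch horizontal and total pixel lengths keyed by
the tip set below the branch). Rectangular layout places tips on evenly
spaced rows (14 px default), inner nodes at the rounded mean of their
children's rows, and x-positions proportional to cumulative branch length
with the shortest branch drawn at `min_branch_px` (8 px default — below
that, junction geometry dominates the signal and no recognizer could
measure reliably); lengths are never drawn below 1 px per unit. Freeform
layout is the equal-angle algorithm with straight edges. Random test
trees come from uniform recursive splitting with exponential branch
lengths (mean 1.0, clipped to [0.3, 3.0] so the length spread stays
renderable at the 8 px floor).

`perturb` applies seeded defects: bilinear rotation with re-thresholding
(ground-truth coordinates are transformed along), 1–3 px gaps cut through
horizontal bars of internal branches (erased lettering crosses the tree
body, and the severed part then carries a whole subtree rather than an
8-pixel tip stub), text-like glyph blocks stamped at tips, and salt
noise.

The drawn root of a bifurcating tree is a plain corner, not a junction,
so its two basal branches merge into one edge on recognition. All
round-trip comparisons are therefore **unrooted**: Robinson–Foulds
distance via dendropy, and per-branch length errors matched by
bipartition with the two basal edges summed.

### What the fixtures do not show

The renderer produces clean anti-aliasing-free lines of known width on a
uniform background. Real scans add JPEG artifacts, varying stroke width,
touching labels, and curved branches; the preprocessing toolbox and edit
scripts exist precisely because those cases need human-guided correction,
and the defect models (rotation, gaps, overlap, noise) probe the
correction machinery rather than prove autonomy. Passing round-trip
batteries establishes that the recognition geometry is sound, not that
arbitrary published figures convert without assistance.

## Problem sizes and numerical notes

The standard batteries are 50 random trees of 4–30 tips for round-trip
recovery (images of roughly 100–700 px a side), 200 random 64×64 blob
images for the skeleton contract, 100 fixtures for the path-tracing
oracle, 200 random trees for Newick round-trip, and 10 rotated fixtures
for the 6° stress case; together they run in a few seconds. Dijkstra
distances compare with a 1e-12 slack when relaxing (pure float
accumulation of 1 and √2 steps); threshold arithmetic is exact-integer
throughout; rotation re-binarizes at intensity 128 after bilinear
interpolation.

## Known limitations

* Circular/polar layouts are out of scope; their branch lengths are not a
  sum of horizontal runs.
* No OCR: tip names must be supplied (position-anchored TSV or config).
* Very short branches (drawn < ~4 px) can vanish into junction clusters;
  the renderer's 8 px floor avoids this by construction, real images may
  not.
* The headless fragment-keeping heuristic (≥ 5 % of the largest
  component) can misclassify a severed tip stub as noise; an explicit
  flood seed plus a manual bridge branch is the reliable correction.
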