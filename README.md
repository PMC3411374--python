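# dendrotrace

**dendrotrace** converts pixel images of phylogenetic trees (PNG, JPEG, GIF)
into machine-readable Newick strings with branch lengths. Published
phylogenies mostly exist only as figures; to reuse them in comparative
analyses they must be digitized — the topology read off the drawing, branch
lengths measured in pixels and calibrated against a scale bar. dendrotrace
is a headless recognition engine plus a scriptable correction layer for
exactly that task, aimed at phylogeneticists and curators of tree
repositories.

## How it works

Recognition runs through a fixed succession of stages, each also available
as a library function:

1. **Load / preprocess** — read the image, convert to grayscale (BT.601
   luminance), optionally filter (median, minimum, blur, sharpen, invert,
   histogram stretch, lighten/darken).
2. **Binarize** — global threshold (Otsu's between-class-variance criterion
   by default, exhaustively scanned over all 256 cut points) or adaptive
   mean-minus-offset local threshold; foreground is dark ink on light paper.
3. **Skeletonize** — Zhang–Suen thinning to a unit-width, 8-connected curve
   skeleton, with a cleanup pass guaranteeing no 2×2 foreground block while
   conserving the number of connected components.
4. **Flood** — select the connected component that is the tree (from a seed
   pixel, or the largest component in headless mode).
5. **Detect nodes** — a skeleton pixel with exactly one foreground neighbor
   is a tip; pixels with ≥ 3 neighbors are branching candidates, clustered
   by adjacency and collapsed to one inner node per junction.
6. **Trace branches** — for every node pair, the geometrically shortest
   gapless skeleton path (axial step 1, diagonal √2) that passes through no
   third node becomes a branch; the resulting graph is validated
   (connected, acyclic, tips of degree 1, inner nodes of degree ≥ 3).
7. **Measure & calibrate** — *freeform* trees use the full path length;
   *rectangular* trees sum only the near-horizontal straight runs (slope
   tolerance 10° by default, so mildly rotated scans still measure).
   A scale bar converts pixels to substitution units; manual overrides mix
   with computed lengths and are flagged in the report.
8. **Name, root, serialize** — tips are named from a position-anchored
   mapping or numbered in reading order; the tree is rooted (leftmost inner
   node by default) and written as Newick with quoted labels where needed.

Corrections an interactive user would paint by hand — pencil/rubber/line/
fill strokes, a white halo that detaches lettering from branches, node
moves, manual bridging branches, length overrides — are supplied as a YAML
*edit script* and replayed deterministically.

The package bundles a fixture renderer (`dendrotrace.render`) that draws
known Newick trees in rectangular or freeform style with exact per-branch
pixel ground truth, plus seeded defect models (rotation, gaps, label
overlap, salt noise), so the whole pipeline is testable by round-trip
without any external images.

## Worked example

Render a known 4-taxon tree to an image, then recognize it back:

```sh
$ python -c "
from dendrotrace import RenderSpec, render_tree, save_image
img, truth = render_tree('((A:2,B:1):1,(C:1.5,D:1):2);', RenderSpec(line_width=1))
save_image(img, 'example.png')
with open('names.tsv','w') as fh:
    for name,(r,c) in truth.tip_positions.items():
        fh.write(f'{r}\t{c}\t{name}\n')"

$ dendrotrace convert example.png --names names.tsv --scale "8,1.0" --report report.tsv
(A:2.05178,B:0.875,(C:1.55178,D:0.875):3.10355);

$ cat report.tsv
branch	length	provenance
0-4	2.05178	scaled
1-4	0.875	scaled
2-5	1.55178	scaled
3-5	0.875	scaled
4-5	3.10355	scaled
```

The recovered topology is the source topology read unrooted: the drawn
root is a plain corner in the image, so its two basal branches merge into
the single internal edge `4-5` whose length (3.10) is the sum of the two
drawn basal lengths (1 + 2). Measured lengths are within one pixel of
truth (the renderer draws the shortest branch at 8 px, so `--scale 8,1.0`
converts pixels back to the original units; B's 1.0 reads as 0.875 because
a junction corner costs about one pixel). Tip names are anchored to image
positions in `names.tsv`; without it, tips are numbered top-to-bottom.

A one-line self-check on a random 12-taxon tree:

```sh
$ dendrotrace roundtrip --tips 12 --seed 4
RF distance: 0
max branch length error: 1.00 px
```

`RF distance: 0` means the recovered unrooted topology is identical to the
source (no bipartition differs).

## Scope

Circular and polar tree layouts are not supported (their branch lengths
are not recoverable from horizontal extents); tip labels are not OCRed —
names come from the user via mapping files; PDF input is rejected (extract
the figure to PNG/JPEG/GIF first).
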