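"""Render known Newick trees to raster images with exact ground truth.

This is the package's synthetic-data generator: every recognition stage can
be exercised end-to-end by drawing a tree whose topology, node coordinates
and per-branch pixel lengths are known exactly, running the pipeline on the
rendered image, and comparing. Two styles are supported, emulating the
figure styles the recognizer targets:

* **rectangular** — horizontal branch bars whose length is proportional to
  branch length, joined by vertical connectors that carry no length;
* **freeform** — straight angled edges (equal-angle layout) whose full drawn
  length is proportional to branch length.

:func:`perturb` adds the defects real scans exhibit — global rotation by a
few degrees, small gaps where lettering was erased, text-like glyph blocks
near tips, salt noise — each seeded and reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy import ndimage as ndi

from .errors import CapacityError, ParameterError
from .preprocess import EditStroke, draw_edit

__all__ = [
    "RenderSpec",
    "BranchTruth",
    "GroundTruth",
    "render_tree",
    "perturb",
    "random_newick",
]


@dataclass(frozen=True)
class RenderSpec:
    """Style and defect parameters for one rendered fixture."""

    style: str = "rectangular"  # rectangular | freeform
    width: int | None = None  # None: sized to fit the tree
    height: int | None = None
    line_width: int = 1
    margin: int = 12
    tip_spacing: int = 14  # rows between adjacent tips (rectangular)
    min_branch_px: int = 8  # enforced minimum drawn branch length
    rotation: float = 0.0  # degrees, applied by perturb()
    gaps: int = 0
    label_overlap: bool = False
    noise: float = 0.0  # salt fraction of background pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.style not in ("rectangular", "freeform"):
            raise ParameterError(f"unknown render style {self.style!r}")
        if self.line_width < 1:
            raise ParameterError("line width must be >= 1")


@dataclass(frozen=True)
class BranchTruth:
    """Ground truth for one branch, keyed by the tip set below it."""

    clade: frozenset[str]
    length_px_horizontal: float
    length_px_total: float
    source_length: float
    bar_row: int | None = None  # rectangular only: row of the horizontal bar
    bar_cols: tuple[int, int] | None = None  # [start, end] inclusive


@dataclass(frozen=True)
class GroundTruth:
    newick: str
    tip_positions: dict[str, tuple[int, int]]  # name -> (row, col)
    inner_positions: tuple[tuple[int, int], ...]
    branches: tuple[BranchTruth, ...]
    gap_positions: tuple[tuple[int, int], ...] = ()

    @property
    def n_tips(self) -> int:
        return len(self.tip_positions)

    def to_json(self) -> str:
        return json.dumps(
            {
                "newick": self.newick,
                "tip_positions": {k: list(v) for k, v in self.tip_positions.items()},
                "inner_positions": [list(p) for p in self.inner_positions],
                "branches": [
                    {
                        "clade": sorted(b.clade),
                        "length_px_horizontal": b.length_px_horizontal,
                        "length_px_total": b.length_px_total,
                        "source_length": b.source_length,
                    }
                    for b in self.branches
                ],
            },
            indent=2,
        )


def _parse(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and (edge.length is None or edge.length <= 0):
            edge.length = 1.0
    return tree


def _leaf_names(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def render_tree(newick: str, spec: RenderSpec) -> tuple[np.ndarray, GroundTruth]:
    """Draw a Newick tree; returns (RGB image, exact ground truth)."""
    tree = _parse(newick)
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise CapacityError("need at least two tips to render a tree")
    if spec.style == "rectangular":
        return _render_rectangular(tree, newick, spec)
    return _render_freeform(tree, newick, spec)


def _render_rectangular(tree, newick: str, spec: RenderSpec):
    leaves = list(tree.leaf_node_iter())
    lw, margin = spec.line_width, spec.margin
    spacing = spec.tip_spacing
    if spec.height is not None:
        usable = spec.height - 2 * margin - lw
        spacing = usable // max(1, len(leaves) - 1)
        if spacing < lw + 3:
            raise CapacityError(
                f"{len(leaves)} tips do not fit into height {spec.height}"
            )
    for i, lf in enumerate(leaves):
        lf.row = margin + i * spacing
    for node in tree.postorder_node_iter():
        if not node.is_leaf():
            rows = [ch.row for ch in node.child_nodes()]
            node.row = int(round(sum(rows) / len(rows)))

    min_len = min(
        e.length for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
    )
    scale = max(1.0, spec.min_branch_px / min_len)
    if spec.width is not None:
        depth = {tree.seed_node: 0.0}
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node:
                depth[node] = depth[node.parent_node] + node.edge.length
        max_depth = max(depth[lf] for lf in leaves)
        scale = min(scale, (spec.width - 2 * margin - lw) / max_depth)
        if min_len * scale < 3:
            raise CapacityError(f"tree too deep for width {spec.width}")
    tree.seed_node.x = margin
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node.x = node.parent_node.x + max(
                min(spec.min_branch_px, 3), int(round(node.edge.length * scale))
            )

    height = spec.height or (margin * 2 + (len(leaves) - 1) * spacing + lw)
    width = spec.width or (max(n.x for n in tree.preorder_node_iter()) + margin + lw)
    img = np.zeros((height, width), dtype=bool)

    branches: list[BranchTruth] = []
    for node in tree.preorder_node_iter():
        kids = node.child_nodes()
        if kids:
            rows = [k.row for k in kids]
            r0, r1 = min(rows), max(rows)
            img[r0 : r1 + lw, node.x : node.x + lw] = True  # vertical connector
        if node is tree.seed_node:
            continue
        xp, xc, r = node.parent_node.x, node.x, node.row
        img[r : r + lw, xp : xc + lw] = True  # horizontal bar
        branches.append(
            BranchTruth(
                clade=_leaf_names(node),
                length_px_horizontal=float(xc - xp),
                length_px_total=float((xc - xp) + abs(r - node.parent_node.row)),
                source_length=float(node.edge.length),
                bar_row=r,
                bar_cols=(xp, xc),
            )
        )

    tip_positions = {lf.taxon.label: (lf.row, lf.x) for lf in leaves}
    inner_positions = tuple(
        (n.row, n.x) for n in tree.preorder_node_iter() if not n.is_leaf()
    )
    truth = GroundTruth(
        newick=newick,
        tip_positions=tip_positions,
        inner_positions=inner_positions,
        branches=tuple(branches),
    )
    return _to_rgb(img), truth


def _render_freeform(tree, newick: str, spec: RenderSpec):
    leaves = list(tree.leaf_node_iter())
    lw = spec.line_width
    # equal-angle layout: wedges proportional to leaf counts
    for node in tree.postorder_node_iter():
        node.n_leaves = 1 if node.is_leaf() else sum(c.n_leaves for c in node.child_nodes())
    total = tree.seed_node.n_leaves
    min_len = min(
        e.length for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
    )
    scale = max(1.0, spec.min_branch_px / min_len)
    tree.seed_node.fpos = (0.0, 0.0)
    tree.seed_node.wedge = (0.0, 2.0 * math.pi)
    for node in tree.preorder_node_iter():
        lo, hi = node.wedge
        start = lo
        for ch in node.child_nodes():
            frac = ch.n_leaves / total * (2.0 * math.pi) if node is tree.seed_node else (
                ch.n_leaves / node.n_leaves * (hi - lo)
            )
            ch.wedge = (start, start + frac)
            ang = start + frac / 2.0
            dist = max(spec.min_branch_px, ch.edge.length * scale)
            pr, pc = node.fpos
            ch.fpos = (pr + dist * math.sin(ang), pc + dist * math.cos(ang))
            start += frac
    rows = [n.fpos[0] for n in tree.preorder_node_iter()]
    cols = [n.fpos[1] for n in tree.preorder_node_iter()]
    off_r = spec.margin - min(rows)
    off_c = spec.margin - min(cols)
    for node in tree.preorder_node_iter():
        node.ipos = (int(round(node.fpos[0] + off_r)), int(round(node.fpos[1] + off_c)))
    height = spec.height or (int(max(rows) - min(rows)) + 2 * spec.margin + lw)
    width = spec.width or (int(max(cols) - min(cols)) + 2 * spec.margin + lw)
    img = np.zeros((height, width), dtype=bool)
    branches: list[BranchTruth] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        p, q = node.parent_node.ipos, node.ipos
        img = draw_edit(img, EditStroke(kind="line", points=[p, q], radius=lw // 2))
        dist = math.hypot(q[0] - p[0], q[1] - p[1])
        branches.append(
            BranchTruth(
                clade=_leaf_names(node),
                length_px_horizontal=float(abs(q[1] - p[1])),
                length_px_total=float(dist),
                source_length=float(node.edge.length),
            )
        )
    tip_positions = {lf.taxon.label: lf.ipos for lf in leaves}
    inner_positions = tuple(n.ipos for n in tree.preorder_node_iter() if not n.is_leaf())
    truth = GroundTruth(
        newick=newick,
        tip_positions=tip_positions,
        inner_positions=inner_positions,
        branches=tuple(branches),
    )
    return _to_rgb(img), truth


def _to_rgb(binary: np.ndarray) -> np.ndarray:
    gray = np.where(binary, 0, 255).astype(np.uint8)
    return np.stack([gray] * 3, axis=-1)


def rotate_point(
    pos: tuple[int, int], old_shape: tuple[int, int], new_shape: tuple[int, int], angle_deg: float
) -> tuple[int, int]:
    """Where a pixel lands after :func:`perturb` rotation (row, col)."""
    th = math.radians(angle_deg)
    cy, cx = (old_shape[0] - 1) / 2.0, (old_shape[1] - 1) / 2.0
    ny, nx = (new_shape[0] - 1) / 2.0, (new_shape[1] - 1) / 2.0
    dy, dx = pos[0] - cy, pos[1] - cx
    return (
        int(round(dy * math.cos(th) - dx * math.sin(th) + ny)),
        int(round(dy * math.sin(th) + dx * math.cos(th) + nx)),
    )


def perturb(
    img: np.ndarray, spec: RenderSpec, truth: GroundTruth | None = None
) -> tuple[np.ndarray, GroundTruth | None]:
    """Apply the spec's defects (gaps, labels, noise, rotation) to a render.

    Returns the perturbed image and, if ground truth was given, the truth
    with node coordinates transformed to match (pixel lengths keep their
    original, pre-rotation values). With no defects configured this is the
    identity.
    """
    rng = np.random.default_rng(spec.seed)
    gray = np.asarray(img)
    if gray.ndim == 3:
        gray = gray[..., 0]
    binary = gray < 128
    gap_positions: list[tuple[int, int]] = []

    if spec.gaps:
        bars = []
        if truth is not None:
            wide = [
                b for b in truth.branches
                if b.bar_cols is not None and b.bar_cols[1] - b.bar_cols[0] >= 16
            ]
            # prefer internal branches: erased lettering crosses the tree
            # body, and the severed part then carries a whole subtree
            bars = [b for b in wide if len(b.clade) >= 2] or wide
        if bars:
            picks = rng.choice(len(bars), size=min(spec.gaps, len(bars)), replace=False)
            for i in sorted(int(x) for x in picks):
                b = bars[i]
                mid = (b.bar_cols[0] + b.bar_cols[1]) // 2
                r = b.bar_row
                gap = int(rng.integers(1, 4))  # 1-3 px
                r0 = max(0, r - 1)
                binary[r0 : r + spec.line_width + 1, mid : mid + gap] = False
                gap_positions.append((r, mid))
        else:  # no bar table: erase around random interior foreground pixels
            fg = np.argwhere(binary)
            for _ in range(spec.gaps):
                r, c = fg[int(rng.integers(len(fg)))]
                gap = int(rng.integers(1, 4))
                binary[max(0, r - 1) : r + 2, c : c + gap] = False

    if spec.label_overlap and truth is not None:
        for name, (r, c) in truth.tip_positions.items():
            glyph_w, glyph_h = 4, 5
            c0 = c + spec.line_width  # touching the tip: simulates overlap
            r0 = max(0, r - glyph_h // 2)
            binary[r0 : r0 + glyph_h, c0 : c0 + glyph_w] = True

    if spec.noise > 0:
        bg = np.argwhere(~binary)
        k = int(spec.noise * len(bg))
        if k:
            picks = bg[rng.choice(len(bg), size=k, replace=False)]
            binary[picks[:, 0], picks[:, 1]] = True

    new_truth = truth
    if truth is not None and (gap_positions or spec.gaps):
        new_truth = replace(truth, gap_positions=tuple(gap_positions))

    if spec.rotation:
        gray_f = np.where(binary, 0.0, 255.0)
        rot = ndi.rotate(gray_f, spec.rotation, reshape=True, order=1, cval=255.0)
        old_shape, new_shape = binary.shape, rot.shape
        binary = rot < 128
        if new_truth is not None:
            tp = {
                k: rotate_point(v, old_shape, new_shape, spec.rotation)
                for k, v in new_truth.tip_positions.items()
            }
            ip = tuple(
                rotate_point(p, old_shape, new_shape, spec.rotation)
                for p in new_truth.inner_positions
            )
            new_truth = replace(new_truth, tip_positions=tp, inner_positions=ip)

    return _to_rgb(binary), new_truth


def random_newick(
    n_tips: int,
    rng: np.random.Generator,
    mean_length: float = 1.0,
    min_length: float = 0.3,
    max_length: float = 3.0,
) -> str:
    """Random binary tree via uniform recursive splitting.

    Branch lengths are exponential with the given mean, clipped to
    [min_length, max_length] so the length spread stays renderable.
    """
    if n_tips < 2:
        raise ParameterError("need at least 2 tips")
    names = [f"L{i + 1}" for i in range(n_tips)]
    rng.shuffle(names)

    def ln() -> float:
        return float(np.clip(rng.exponential(mean_length), min_length, max_length))

    def build(group: list[str]) -> str:
        if len(group) == 1:
            return f"{group[0]}:{ln():.4f}"
        k = int(rng.integers(1, len(group)))
        return f"({build(group[:k])},{build(group[k:])}):{ln():.4f}"

    k = int(rng.integers(1, n_tips))
    left, right = names[:k], names[k:]
    return f"({build(left)},{build(right)});"
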