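"""Detect tips and branching points on the skeleton; apply node edits.

On a unit-width skeleton the tree's anatomy is local: a foreground pixel with
exactly one foreground 8-neighbor is the end of a line (a tip / taxon), and a
pixel with three or more neighbors is a candidate branching location. Because
junctions of thinned lines often occupy a small cluster of adjacent candidate
pixels, candidates are grouped by 8-connectivity and each cluster is reduced
to a single inner node at its centroid, snapped to the nearest cluster pixel
(ties broken by row, then column) so that node positions always lie on the
skeleton.

Pixels with exactly two neighbors are path interior and never become nodes;
isolated pixels (zero neighbors) are ignored with a warning — they are noise,
not taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
from scipy import ndimage as ndi

from .component import ComponentMask
from .errors import EditError, PositionError
from .skeleton import Skeleton, neighbor_counts

__all__ = ["TreeNode", "NodeSet", "detect_nodes", "edit_nodes", "NodeEdit"]

logger = logging.getLogger(__name__)

_S8 = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class TreeNode:
    """One logical node; ``cluster`` is the full set of skeleton pixels that
    belong to the junction (a thinned crossing often occupies several
    adjacent candidate pixels — the whole cluster acts as the node when
    paths are traced)."""

    id: int
    pos: tuple[int, int]
    kind: Literal["tip", "inner"]
    origin: Literal["auto", "manual"] = "auto"
    cluster: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.cluster:
            object.__setattr__(self, "cluster", (self.pos,))


@dataclass(frozen=True)
class NodeSet:
    nodes: tuple[TreeNode, ...] = ()

    def __iter__(self):
        return iter(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    def by_id(self, node_id: int) -> TreeNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise EditError(f"no node with id {node_id}")

    @property
    def tips(self) -> tuple[TreeNode, ...]:
        return tuple(n for n in self.nodes if n.kind == "tip")

    @property
    def inner(self) -> tuple[TreeNode, ...]:
        return tuple(n for n in self.nodes if n.kind == "inner")

    def positions(self) -> dict[tuple[int, int], int]:
        return {n.pos: n.id for n in self.nodes}

    def cluster_map(self) -> dict[tuple[int, int], int]:
        """Every node-owned pixel (whole junction clusters) -> node id."""
        out: dict[tuple[int, int], int] = {}
        for n in self.nodes:
            for p in n.cluster:
                out[p] = n.id
        return out


def detect_nodes(skel: Skeleton, mask: ComponentMask) -> NodeSet:
    """Find tip and branching locations on the masked skeleton."""
    fg = skel.pixels & mask.member
    counts = neighbor_counts(fg)
    nodes: list[TreeNode] = []
    next_id = 0

    n_isolated = int(((counts == 0) & fg).sum())
    if n_isolated:
        logger.warning("ignoring %d isolated foreground pixel(s) (noise)", n_isolated)

    for r, c in np.argwhere((counts == 1) & fg):
        nodes.append(TreeNode(id=next_id, pos=(int(r), int(c)), kind="tip"))
        next_id += 1

    candidates = (counts >= 3) & fg
    labels, n_clusters = ndi.label(candidates, structure=_S8)
    for lbl in range(1, n_clusters + 1):
        pts = np.argwhere(labels == lbl)
        centroid = pts.mean(axis=0)
        d2 = ((pts - centroid) ** 2).sum(axis=1)
        # snap to nearest cluster pixel; ties by row, then col
        order = np.lexsort((pts[:, 1], pts[:, 0], d2))
        r, c = pts[order[0]]
        cluster = tuple((int(a), int(b)) for a, b in pts)
        nodes.append(
            TreeNode(id=next_id, pos=(int(r), int(c)), kind="inner", cluster=cluster)
        )
        next_id += 1
    return NodeSet(nodes=tuple(nodes))


@dataclass(frozen=True)
class NodeEdit:
    """One node correction: add(pos, kind), move(id, pos) or remove(id)."""

    action: Literal["add", "move", "remove"]
    node_id: int | None = None
    pos: tuple[int, int] | None = None
    kind: Literal["tip", "inner"] | None = None


def _check_on_mask(pos: tuple[int, int], mask: ComponentMask) -> None:
    r, c = pos
    h, w = mask.member.shape
    if not (0 <= r < h and 0 <= c < w) or not mask.member[r, c]:
        raise PositionError(f"position ({r},{c}) is not on the tree component")


def edit_nodes(ns: NodeSet, edits: Iterable[NodeEdit], mask: ComponentMask) -> NodeSet:
    """Apply user node corrections in order; touched nodes become manual."""
    nodes = list(ns.nodes)
    next_id = max((n.id for n in nodes), default=-1) + 1
    for e in edits:
        if e.action == "add":
            if e.pos is None or e.kind is None:
                raise EditError("add edit needs pos and kind")
            _check_on_mask(e.pos, mask)
            if any(n.pos == tuple(e.pos) for n in nodes):
                raise EditError(f"a node already exists at {e.pos}")
            nodes.append(TreeNode(id=next_id, pos=tuple(e.pos), kind=e.kind, origin="manual"))
            next_id += 1
        elif e.action == "move":
            if e.node_id is None or e.pos is None:
                raise EditError("move edit needs node_id and pos")
            _check_on_mask(e.pos, mask)
            idx = _index_of(nodes, e.node_id)
            nodes[idx] = replace(
                nodes[idx], pos=tuple(e.pos), origin="manual", cluster=(tuple(e.pos),)
            )
        elif e.action == "remove":
            if e.node_id is None:
                raise EditError("remove edit needs node_id")
            nodes.pop(_index_of(nodes, e.node_id))
        else:
            raise EditError(f"unknown node edit action {e.action!r}")
    return NodeSet(nodes=tuple(nodes))


def _index_of(nodes: list[TreeNode], node_id: int) -> int:
    for i, n in enumerate(nodes):
        if n.id == node_id:
            return i
    raise EditError(f"no node with id {node_id}")
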