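"""Recover branches as shortest gapless skeleton paths between nodes.

A branch of the drawn tree is a foreground path on the skeleton connecting
two nodes without passing through any third node ("node-blocked"): without
that restriction every pair of tips would be joined by a path and the result
would not be a tree. For each connected node pair the geometrically shortest
path is selected — axial steps count 1, diagonal steps sqrt(2) — via Dijkstra
on the pixel adjacency graph with a fixed neighbor scan order, which makes
tie-breaking between equal-length paths deterministic.

Pairs with no node-free path simply get no branch; structural problems
(disconnection, cycles, bad degrees) are reported by :func:`validate`, which
replaces the visual inspection a GUI user would perform.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .component import ComponentMask
from .errors import EditError
from .nodes import NodeSet
from .skeleton import Skeleton

__all__ = ["Branch", "TreeGraph", "Diagnostic", "trace_branches", "add_manual_branch", "validate"]

_SQRT2 = math.sqrt(2.0)
# fixed scan order: axial first, then diagonals, each in (row, col) order
_NEIGHBORS = [(-1, 0), (0, -1), (0, 1), (1, 0), (-1, -1), (-1, 1), (1, -1), (1, 1)]


@dataclass(frozen=True)
class Branch:
    """One traced branch: endpoint node ids plus its pixel path.

    ``path`` runs from the position of ``endpoints[0]`` to ``endpoints[1]``;
    consecutive pixels are 8-adjacent and interior pixels are never node
    positions. Manually added branches have an empty path and carry
    ``manual_length`` (in pixels) instead.
    """

    endpoints: tuple[int, int]
    path: tuple[tuple[int, int], ...] = ()
    manual_length: float | None = None

    @property
    def key(self) -> tuple[int, int]:
        a, b = self.endpoints
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class TreeGraph:
    nodes: NodeSet
    branches: tuple[Branch, ...] = ()

    def degree(self, node_id: int) -> int:
        return sum(1 for b in self.branches if node_id in b.endpoints)

    def neighbors(self, node_id: int) -> list[int]:
        out = []
        for b in self.branches:
            a, bb = b.endpoints
            if a == node_id:
                out.append(bb)
            elif bb == node_id:
                out.append(a)
        return out

    def branch_between(self, a: int, b: int) -> Branch | None:
        key = (a, b) if a <= b else (b, a)
        for br in self.branches:
            if br.key == key:
                return br
        return None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.id, pos=n.pos, kind=n.kind)
        for b in self.branches:
            g.add_edge(*b.endpoints, branch=b)
        return g


def _dijkstra_from(
    src: tuple[int, int],
    source_id: int,
    owner: dict[tuple[int, int], int],
    node_pos: dict[int, tuple[int, int]],
    fg: np.ndarray,
) -> dict[int, tuple[float, tuple[tuple[int, int], ...]]]:
    """Shortest node-blocked paths from one node to every reachable node.

    ``owner`` maps every node-owned pixel (whole junction clusters) to its
    node id. A pixel owned by another node may be entered, and the search
    may continue *within that node's cluster only*, so a path terminates at
    the node's canonical position without ever crossing the junction into
    territory beyond it. Pixels of the source's own cluster are free.
    """
    h, w = fg.shape
    dist: dict[tuple[int, int], float] = {src: 0.0}
    pred: dict[tuple[int, int], tuple[int, int]] = {}
    done: set[tuple[int, int]] = set()
    heap: list[tuple[float, tuple[int, int]]] = [(0.0, src)]
    found: dict[int, tuple[float, tuple[tuple[int, int], ...]]] = {}
    while heap:
        d, p = heapq.heappop(heap)
        if p in done:
            continue
        done.add(p)
        hit = owner.get(p)
        blocked = hit is not None and hit != source_id
        if blocked and p == node_pos[hit] and hit not in found:
            path = [p]
            while path[-1] != src:
                path.append(pred[path[-1]])
            found[hit] = (d, tuple(reversed(path)))
        r, c = p
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and fg[rr, cc]:
                q = (rr, cc)
                if q in done:
                    continue
                if blocked and owner.get(q) != hit:
                    continue  # may not leave another node's cluster
                nd = d + (1.0 if dr == 0 or dc == 0 else _SQRT2)
                if nd < dist.get(q, math.inf) - 1e-12:
                    dist[q] = nd
                    pred[q] = p
                    heapq.heappush(heap, (nd, q))
    return found


def trace_branches(skel: Skeleton, mask: ComponentMask, ns: NodeSet) -> TreeGraph:
    """Trace the shortest node-free path between every connected node pair."""
    fg = (skel.pixels & mask.member).copy()
    owner = ns.cluster_map()
    # node pixels must be traversable even if an edit moved one slightly
    for (r, c) in owner:
        fg[r, c] = True
    node_pos = {n.id: n.pos for n in ns}
    branches: dict[tuple[int, int], Branch] = {}
    for node in sorted(ns, key=lambda n: n.id):
        reached = _dijkstra_from(node.pos, node.id, owner, node_pos, fg)
        for other_id, (_, path) in reached.items():
            key = (node.id, other_id) if node.id <= other_id else (other_id, node.id)
            if key not in branches:  # first (smaller source id) wins
                if path[0] != node.pos:
                    path = tuple(reversed(path))
                branches[key] = Branch(endpoints=(node.id, other_id), path=path)
    ordered = tuple(branches[k] for k in sorted(branches))
    return TreeGraph(nodes=ns, branches=ordered)


def add_manual_branch(g: TreeGraph, a: int, b: int, length: float) -> TreeGraph:
    """Add a user-drawn branch with a user-specified pixel length."""
    if a == b:
        raise EditError("a manual branch needs two distinct endpoints")
    g.nodes.by_id(a)
    g.nodes.by_id(b)
    if g.branch_between(a, b) is not None:
        raise EditError(f"branch between {a} and {b} already exists")
    if not length > 0:
        raise EditError(f"manual branch length must be positive, got {length}")
    new = Branch(endpoints=(a, b), path=(), manual_length=float(length))
    return TreeGraph(nodes=g.nodes, branches=g.branches + (new,))


@dataclass(frozen=True)
class Diagnostic:
    """One structural problem found by :func:`validate`."""

    kind: str  # disconnected | cycle | inner_degree | tip_degree | isolated
    message: str
    data: tuple = field(default_factory=tuple)


def validate(g: TreeGraph) -> list[Diagnostic]:
    """Check the TreeGraph invariants; an empty list means a valid tree."""
    out: list[Diagnostic] = []
    nxg = g.to_networkx()
    if len(nxg) == 0:
        return [Diagnostic("disconnected", "graph has no nodes")]
    comps = [sorted(c) for c in nx.connected_components(nxg)]
    if len(comps) > 1:
        out.append(
            Diagnostic(
                "disconnected",
                f"graph splits into {len(comps)} components; "
                "bridge them with a pencil stroke or a manual branch",
                tuple(tuple(c) for c in comps),
            )
        )
    for cycle in nx.cycle_basis(nxg):
        out.append(Diagnostic("cycle", f"cycle through nodes {cycle}", tuple(cycle)))
    for n in g.nodes:
        deg = nxg.degree(n.id)
        if deg == 0:
            out.append(Diagnostic("isolated", f"node {n.id} at {n.pos} has no branches", (n.id,)))
        elif n.kind == "tip" and deg != 1:
            out.append(
                Diagnostic("tip_degree", f"tip {n.id} at {n.pos} has degree {deg}", (n.id, deg))
            )
        elif n.kind == "inner" and deg < 3:
            out.append(
                Diagnostic(
                    "inner_degree",
                    f"inner node {n.id} at {n.pos} has degree {deg} (< 3); "
                    "remove it or add the missing branch",
                    (n.id, deg),
                )
            )
    return out
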