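"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own vectorized code paths: neighbor
counting and clustering are plain Python loops, flood fill is a literal BFS,
Otsu is a per-pixel partition scan, and shortest paths come from networkx.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from scipy import ndimage as ndi

SQRT2 = math.sqrt(2.0)
OFFSETS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def random_blobs(rng: np.random.Generator, shape=(64, 64), density=0.35) -> np.ndarray:
    img = rng.random(shape) < density
    return ndi.binary_closing(img)


def brute_force_nodes(fg: np.ndarray):
    """(tips, clusters): tip coords and candidate clusters with snap rule."""
    h, w = fg.shape

    def count(r, c):
        n = 0
        for dr, dc in OFFSETS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and fg[rr, cc]:
                n += 1
        return n

    tips = []
    candidates = set()
    for r in range(h):
        for c in range(w):
            if fg[r, c]:
                k = count(r, c)
                if k == 1:
                    tips.append((r, c))
                elif k >= 3:
                    candidates.add((r, c))
    clusters = []
    seen = set()
    for start in sorted(candidates):
        if start in seen:
            continue
        group = []
        queue = [start]
        seen.add(start)
        while queue:
            p = queue.pop(0)
            group.append(p)
            for dr, dc in OFFSETS8:
                q = (p[0] + dr, p[1] + dc)
                if q in candidates and q not in seen:
                    seen.add(q)
                    queue.append(q)
        centroid = (
            sum(p[0] for p in group) / len(group),
            sum(p[1] for p in group) / len(group),
        )
        snapped = min(
            group,
            key=lambda p: ((p[0] - centroid[0]) ** 2 + (p[1] - centroid[1]) ** 2, p[0], p[1]),
        )
        clusters.append((snapped, frozenset(group)))
    return tips, clusters


def bfs_flood(fg: np.ndarray, seed) -> set:
    """Literal breadth-first flood on the 8-neighbor pixel graph."""
    h, w = fg.shape
    seen = {seed}
    queue = [seed]
    while queue:
        r, c = queue.pop(0)
        for dr, dc in OFFSETS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and fg[rr, cc] and (rr, cc) not in seen:
                seen.add((rr, cc))
                queue.append((rr, cc))
    return seen


def otsu_brute_force(img: np.ndarray) -> int:
    """Scan all 256 cut points, computing class stats from raw pixels."""
    from fractions import Fraction

    vals = [int(v) for v in np.asarray(img).ravel()]
    best_t, best = 0, Fraction(0)
    found = False
    for t in range(1, 256):
        lo = [v for v in vals if v < t]
        hi = [v for v in vals if v >= t]
        if not lo or not hi:
            continue
        mu0 = Fraction(sum(lo), len(lo))
        mu1 = Fraction(sum(hi), len(hi))
        var = Fraction(len(lo) * len(hi), len(vals) ** 2) * (mu0 - mu1) ** 2
        if var > best:
            best, best_t, found = var, t, True
    if not found:
        return int(min(vals)) if vals else 0
    return best_t


def pixel_graph(fg: np.ndarray) -> nx.Graph:
    pts = {tuple(p) for p in np.argwhere(fg)}
    g = nx.Graph()
    g.add_nodes_from(pts)
    for (r, c) in pts:
        for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
            q = (r + dr, c + dc)
            if q in pts:
                g.add_edge((r, c), q, weight=1.0 if dr == 0 or dc == 0 else SQRT2)
    return g


def blocked_shortest_length(graph: nx.Graph, a_pos, b_pos, blocked) -> float:
    sub = graph.subgraph([p for p in graph if p not in blocked])
    return nx.dijkstra_path_length(sub, a_pos, b_pos)
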