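"""Name tips, root the tree graph, and serialize to Newick.

The traced :class:`~dendrotrace.trace.TreeGraph` is unrooted; publication
figures are read rooted, so a root is chosen (by default the leftmost inner
node — rectangular phylogenies grow left to right with the root at the left)
and the tree is oriented away from it. Child order in the Newick string is
the clockwise angular order, around each node, of the first pixel step of
each child branch: geometry-derived and therefore stable across runs.

Tip names come from an explicit mapping or, following common digitization
practice, consecutive numbers assigned in reading order (top-to-bottom, then
left-to-right). Names containing Newick metacharacters are single-quoted
with internal quotes doubled; the output re-parses to the identical tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

from .errors import MappingError, RootingError
from .trace import TreeGraph, validate

__all__ = ["AUTO", "PhyloTree", "assign_names", "root_tree", "to_newick"]

logger = logging.getLogger(__name__)

AUTO = "auto"

_NEEDS_QUOTE = set(" ():;,[]'")


@dataclass(frozen=True)
class PhyloTree:
    """A rooted, named, length-annotated tree ready for serialization."""

    root: int
    children: Mapping[int, tuple[int, ...]]
    names: Mapping[int, str]
    lengths: Mapping[int, float] = field(default_factory=dict)  # node -> length to parent

    def tips(self) -> list[int]:
        return [n for n in self._preorder() if not self.children.get(n)]

    def _preorder(self) -> list[int]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.children.get(n, ())))
        return out


def assign_names(
    g: TreeGraph, mapping: Mapping[int, str] | str = AUTO
) -> dict[int, str]:
    """Name every tip; unnamed tips get consecutive numbers in reading order."""
    tip_ids = {n.id for n in g.nodes.tips}
    explicit: dict[int, str] = {}
    if mapping != AUTO:
        for node_id, name in mapping.items():
            if node_id not in tip_ids:
                raise MappingError(f"node {node_id} is not a tip; only tips get names")
            explicit[node_id] = str(name)
    ordered = sorted(g.nodes.tips, key=lambda n: n.pos)  # (row, col): reading order
    names: dict[int, str] = {}
    counter = 1
    for tip in ordered:
        if tip.id in explicit:
            names[tip.id] = explicit[tip.id]
        else:
            names[tip.id] = str(counter)
        counter += 1
    # de-duplicate with suffixes, warning the user
    seen: dict[str, int] = {}
    for tip in ordered:
        name = names[tip.id]
        if name in seen:
            seen[name] += 1
            new = f"{name}_{seen[name]}"
            logger.warning("duplicate tip name %r renamed to %r", name, new)
            names[tip.id] = new
        else:
            seen[name] = 0
    return names


def _branch_direction(g: TreeGraph, parent: int, child: int) -> tuple[float, float]:
    """Unit-free direction (dr, dc) of the branch leaving ``parent``."""
    b = g.branch_between(parent, child)
    ppos = g.nodes.by_id(parent).pos
    if b is not None and len(b.path) >= 2:
        path = b.path if b.endpoints[0] == parent else tuple(reversed(b.path))
        q = path[1]
        return (q[0] - ppos[0], q[1] - ppos[1])
    cpos = g.nodes.by_id(child).pos
    return (cpos[0] - ppos[0], cpos[1] - ppos[1])


def _clockwise_from_north(direction: tuple[float, float]) -> float:
    dr, dc = direction
    # image rows grow downward: east = +col, north = -row
    return math.atan2(dc, -dr) % (2.0 * math.pi)


def root_tree(
    g: TreeGraph,
    root: int | str = AUTO,
    names: Mapping[int, str] | None = None,
    branch_lengths: Mapping[tuple[int, int], float] | None = None,
) -> PhyloTree:
    """Orient the validated tree graph away from a chosen root node."""
    diagnostics = validate(g)
    if diagnostics:
        raise RootingError(
            "graph is not a valid tree: " + "; ".join(d.message for d in diagnostics)
        )
    inner = g.nodes.inner
    if root == AUTO:
        if inner:
            root_id = min(inner, key=lambda n: (n.pos[1], n.pos[0], n.id)).id
        else:  # degenerate two-tip tree
            root_id = min(g.nodes, key=lambda n: (n.pos[1], n.pos[0], n.id)).id
    else:
        node = g.nodes.by_id(int(root))
        if node.kind == "tip" and inner:
            raise RootingError(f"node {root} is a tip; choose an inner node as root")
        root_id = node.id
    if names is None:
        names = assign_names(g)
    children: dict[int, tuple[int, ...]] = {}
    lengths: dict[int, float] = {}
    blens = {tuple(sorted(k)): v for k, v in (branch_lengths or {}).items()}
    seen = {root_id}
    stack = [root_id]
    while stack:
        parent = stack.pop()
        kids = [k for k in g.neighbors(parent) if k not in seen]
        kids.sort(key=lambda k: (_clockwise_from_north(_branch_direction(g, parent, k)), k))
        children[parent] = tuple(kids)
        for k in kids:
            seen.add(k)
            key = (parent, k) if parent <= k else (k, parent)
            if key in blens:
                lengths[k] = float(blens[key])
            stack.extend([k])
    return PhyloTree(root=root_id, children=children, names=dict(names), lengths=lengths)


def _format_name(name: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _format_length(value: float, precision: int) -> str:
    return f"{value:.{precision}g}"


def to_newick(t: PhyloTree, with_lengths: bool = True, precision: int = 6) -> str:
    """Serialize to a Newick string terminated by ';'."""

    def render(node: int) -> str:
        kids = t.children.get(node, ())
        if kids:
            body = "(" + ",".join(render(k) for k in kids) + ")"
            label = ""
        else:
            body = ""
            label = _format_name(t.names.get(node, str(node)))
        s = body + label
        if with_lengths and node in t.lengths:
            s += ":" + _format_length(t.lengths[node], precision)
        return s

    return render(t.root) + ";"
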