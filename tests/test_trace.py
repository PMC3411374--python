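import numpy as np
import pytest

import _oracles
from dendrotrace.component import flood, largest_component
from dendrotrace.errors import EditError
from dendrotrace.lengths import path_length_freeform
from dendrotrace.nodes import NodeSet, TreeNode, detect_nodes
from dendrotrace.preprocess import threshold_global
from dendrotrace.raster_io import to_grayscale
from dendrotrace.render import RenderSpec, random_newick, render_tree
from dendrotrace.skeleton import Skeleton, skeletonize
from dendrotrace.trace import Branch, TreeGraph, add_manual_branch, trace_branches, validate


def recognize(img):
    skel = skeletonize(threshold_global(to_grayscale(img)))
    mask = largest_component(skel)
    ns = detect_nodes(skel, mask)
    return skel, mask, ns


class TestTraceBranches:
    def test_plus_yields_four_center_branches(self, plus_skeleton):
        skel = Skeleton(pixels=plus_skeleton, parent=plus_skeleton)
        mask = flood(skel, (5, 5))
        ns = detect_nodes(skel, mask)
        g = trace_branches(skel, mask, ns)
        center = ns.inner[0].id
        assert len(g.branches) == 4
        assert all(center in b.endpoints for b in g.branches)
        for b in g.branches:
            assert b.path[0] == ns.by_id(b.endpoints[0]).pos
            assert b.path[-1] == ns.by_id(b.endpoints[1]).pos

    def test_line_single_branch_covers_whole_line(self, line_skeleton):
        skel = Skeleton(pixels=line_skeleton, parent=line_skeleton)
        mask = flood(skel, (2, 5))
        ns = detect_nodes(skel, mask)
        g = trace_branches(skel, mask, ns)
        assert len(g.branches) == 1
        assert len(g.branches[0].path) == 10

    def test_interior_pixels_never_node_positions(self, rng):
        nwk = random_newick(8, rng)
        img, _ = render_tree(nwk, RenderSpec(seed=0))
        skel, mask, ns = recognize(img)
        g = trace_branches(skel, mask, ns)
        node_positions = set(ns.positions())
        for b in g.branches:
            for p in b.path[1:-1]:
                assert p not in node_positions

    def test_path_lengths_equal_blocked_dijkstra_oracle(self, rng):
        for seed in range(8):
            nwk = random_newick(int(rng.integers(4, 9)), rng)
            img, _ = render_tree(nwk, RenderSpec(seed=seed))
            skel, mask, ns = recognize(img)
            g = trace_branches(skel, mask, ns)
            fg = skel.pixels & mask.member
            graph = _oracles.pixel_graph(fg)
            owner = ns.cluster_map()
            for b in g.branches:
                a_id, b_id = b.endpoints
                blocked = {p for p, i in owner.items() if i not in (a_id, b_id)}
                d = _oracles.blocked_shortest_length(
                    graph, ns.by_id(a_id).pos, ns.by_id(b_id).pos, blocked
                )
                assert path_length_freeform(b) == pytest.approx(d, abs=1e-9)

    def test_rendered_tree_recovers_source_degree_sequence(self, rng):
        nwk = "((A:1,B:1):1,(C:1,D:1):1);"
        img, _ = render_tree(nwk, RenderSpec(seed=1))
        skel, mask, ns = recognize(img)
        g = trace_branches(skel, mask, ns)
        assert not validate(g)
        # the drawn root is a plain corner, so only the two clade junctions
        # survive as inner nodes: 4 tips of degree 1, 2 inner of degree 3
        degs = sorted(g.degree(n.id) for n in ns)
        assert degs == [1, 1, 1, 1, 3, 3]


def toy_graph():
    ns = NodeSet(
        nodes=(
            TreeNode(0, (0, 0), "tip"),
            TreeNode(1, (0, 10), "tip"),
            TreeNode(2, (10, 0), "tip"),
            TreeNode(3, (5, 5), "inner"),
        )
    )
    branches = tuple(
        Branch(endpoints=(i, 3), path=(), manual_length=5.0) for i in range(3)
    )
    return TreeGraph(nodes=ns, branches=branches)


class TestManualBranchesAndValidate:
    def test_manual_branch_bridges_components(self):
        ns = NodeSet(
            nodes=(
                TreeNode(0, (0, 0), "tip"),
                TreeNode(1, (0, 5), "tip"),
                TreeNode(2, (5, 0), "tip"),
                TreeNode(3, (5, 5), "tip"),
            )
        )
        g = TreeGraph(
            nodes=ns,
            branches=(
                Branch(endpoints=(0, 1), path=(), manual_length=5.0),
                Branch(endpoints=(2, 3), path=(), manual_length=5.0),
            ),
        )
        diags = validate(g)
        assert any(d.kind == "disconnected" for d in diags)
        bridged = add_manual_branch(g, 1, 2, 4.2)
        assert not any(d.kind == "disconnected" for d in validate(bridged))

    def test_adding_branch_to_valid_tree_reports_cycle(self):
        g = toy_graph()
        assert validate(g) == []
        cyclic = add_manual_branch(g, 0, 1, 1.0)
        assert any(d.kind == "cycle" for d in validate(cyclic))

    def test_duplicate_and_nonpositive_rejected(self):
        g = toy_graph()
        with pytest.raises(EditError):
            add_manual_branch(g, 0, 3, 1.0)  # already present
        with pytest.raises(EditError):
            add_manual_branch(g, 0, 1, 0.0)

    def test_two_disjoint_edges_one_disconnection_with_two_components(self):
        ns = NodeSet(
            nodes=(
                TreeNode(0, (0, 0), "tip"),
                TreeNode(1, (0, 5), "tip"),
                TreeNode(2, (5, 0), "tip"),
                TreeNode(3, (5, 5), "tip"),
            )
        )
        g = TreeGraph(
            nodes=ns,
            branches=(
                Branch(endpoints=(0, 1), path=(), manual_length=1.0),
                Branch(endpoints=(2, 3), path=(), manual_length=1.0),
            ),
        )
        disc = [d for d in validate(g) if d.kind == "disconnected"]
        assert len(disc) == 1
        assert len(disc[0].data) == 2

    def test_triangle_reports_cycle(self):
        ns = NodeSet(
            nodes=(
                TreeNode(0, (0, 0), "inner"),
                TreeNode(1, (0, 5), "inner"),
                TreeNode(2, (5, 0), "inner"),
            )
        )
        g = TreeGraph(
            nodes=ns,
            branches=(
                Branch(endpoints=(0, 1), path=(), manual_length=1.0),
                Branch(endpoints=(1, 2), path=(), manual_length=1.0),
                Branch(endpoints=(0, 2), path=(), manual_length=1.0),
            ),
        )
        assert any(d.kind == "cycle" for d in validate(g))
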