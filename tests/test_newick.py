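import dendropy
import numpy as np
import pytest

from dendrotrace.errors import MappingError, RootingError
from dendrotrace.metrics import bipartition_lengths, rf_distance
from dendrotrace.newick import AUTO, PhyloTree, assign_names, root_tree, to_newick
from dendrotrace.nodes import NodeSet, TreeNode
from dendrotrace.trace import Branch, TreeGraph


def star_graph():
    """Center with four tips at the compass points."""
    ns = NodeSet(
        nodes=(
            TreeNode(0, (0, 5), "tip"),  # north
            TreeNode(1, (5, 9), "tip"),  # east
            TreeNode(2, (9, 5), "tip"),  # south
            TreeNode(3, (5, 0), "tip"),  # west
            TreeNode(4, (5, 5), "inner"),
        )
    )
    branches = tuple(Branch(endpoints=(i, 4), path=(), manual_length=5.0) for i in range(4))
    return TreeGraph(nodes=ns, branches=branches)


def caterpillar_graph():
    """Two cherries joined by an internal edge: ((A,B),(C,D))."""
    ns = NodeSet(
        nodes=(
            TreeNode(0, (0, 20), "tip"),
            TreeNode(1, (4, 20), "tip"),
            TreeNode(2, (8, 20), "tip"),
            TreeNode(3, (12, 20), "tip"),
            TreeNode(4, (2, 10), "inner"),
            TreeNode(5, (10, 12), "inner"),
        )
    )
    branches = (
        Branch(endpoints=(0, 4), path=(), manual_length=5.0),
        Branch(endpoints=(1, 4), path=(), manual_length=5.0),
        Branch(endpoints=(2, 5), path=(), manual_length=5.0),
        Branch(endpoints=(3, 5), path=(), manual_length=5.0),
        Branch(endpoints=(4, 5), path=(), manual_length=5.0),
    )
    return TreeGraph(nodes=ns, branches=branches)


class TestAssignNames:
    def test_auto_numbers_in_reading_order(self):
        g = star_graph()
        names = assign_names(g, AUTO)
        # top-to-bottom by row, ties by col: north, west, east, south
        assert names[0] == "1"
        assert names[3] == "2"
        assert names[1] == "3"
        assert names[2] == "4"

    def test_explicit_name_overrides_one_tip(self):
        g = star_graph()
        names = assign_names(g, {0: "Homo_sapiens"})
        assert names[0] == "Homo_sapiens"
        assert sorted(names[k] for k in (1, 2, 3)) == ["2", "3", "4"]

    def test_naming_inner_node_rejected(self):
        with pytest.raises(MappingError):
            assign_names(star_graph(), {4: "nope"})

    def test_duplicate_names_suffixed(self):
        names = assign_names(star_graph(), {0: "X", 1: "X"})
        assert names[0] == "X"
        assert names[1] == "X_1"


class TestRootTree:
    def test_star_rooted_at_center_single_level(self):
        g = star_graph()
        t = root_tree(g, root=4, names={0: "A", 1: "B", 2: "C", 3: "D"})
        assert t.root == 4
        assert len(t.children[4]) == 4
        # children clockwise from north: N, E, S, W
        assert [t.names[c] for c in t.children[4]] == ["A", "B", "C", "D"]
        assert to_newick(t, with_lengths=False) == "(A,B,C,D);"

    def test_root_choice_does_not_change_unrooted_topology(self):
        g = caterpillar_graph()
        names = {0: "A", 1: "B", 2: "C", 3: "D"}
        n4 = to_newick(root_tree(g, root=4, names=names))
        n5 = to_newick(root_tree(g, root=5, names=names))
        assert rf_distance(n4, n5) == 0

    def test_auto_root_is_leftmost_inner_node(self):
        g = caterpillar_graph()
        t = root_tree(g)
        assert t.root == 4  # col 10 < col 12

    def test_tip_as_root_rejected(self):
        with pytest.raises(RootingError):
            root_tree(star_graph(), root=0)

    def test_invalid_graph_rejected(self):
        g = star_graph()
        broken = TreeGraph(nodes=g.nodes, branches=g.branches[:-1])  # west tip isolated
        with pytest.raises(RootingError):
            root_tree(broken)


class TestToNewick:
    def test_caterpillar_canonical_form(self):
        t = PhyloTree(
            root=0,
            children={0: (1, 2), 1: (3, 4)},
            names={3: "A", 4: "B", 2: "C"},
            lengths={1: 3.0, 3: 1.0, 4: 2.0, 2: 4.0},
        )
        assert to_newick(t) == "((A:1,B:2):3,C:4);"

    def test_quoted_name_survives_independent_parser(self):
        t = PhyloTree(root=0, children={0: (1, 2)}, names={1: "sp. nov", 2: "B"})
        s = to_newick(t)
        assert "'sp. nov'" in s
        parsed = dendropy.Tree.get(data=s, schema="newick")
        labels = {lf.taxon.label for lf in parsed.leaf_node_iter()}
        assert labels == {"sp. nov", "B"}

    def test_metacharacters_and_quotes_round_trip(self):
        for name in ["a b", "x(y)", "semi;colon", "quo'te", "com,ma"]:
            t = PhyloTree(root=0, children={0: (1, 2)}, names={1: name, 2: "B"})
            parsed = dendropy.Tree.get(data=to_newick(t), schema="newick")
            labels = {lf.taxon.label for lf in parsed.leaf_node_iter()}
            assert labels == {name, "B"}


def random_phylotree(rng, n_tips, with_odd_names=False):
    next_id = [0]

    def new_id():
        next_id[0] += 1
        return next_id[0] - 1

    children = {}
    names = {}
    lengths = {}
    pool = ["T%d" % i for i in range(n_tips)]
    if with_odd_names:
        pool[0] = "sp. nov"
        if n_tips > 2:
            pool[1] = "x(paren)"

    def build(tips):
        nid = new_id()
        if len(tips) == 1:
            names[nid] = tips[0]
        else:
            k = int(rng.integers(1, len(tips)))
            kids = [build(tips[:k]), build(tips[k:])]
            children[nid] = tuple(kids)
        lengths[nid] = float(np.round(rng.uniform(0.01, 9.99), 4))
        return nid

    root = build(pool)
    lengths.pop(root)
    return PhyloTree(root=root, children=children, names=names, lengths=lengths)


def canon_dendropy(node):
    kids = node.child_nodes()
    length = None if node.edge.length is None else f"{node.edge.length:.6g}"
    if not kids:
        return (node.taxon.label if node.taxon else node.label, length)
    return (frozenset(canon_dendropy(k) for k in kids), length)


def canon_phylo(t, node):
    kids = t.children.get(node, ())
    length = f"{t.lengths[node]:.6g}" if node in t.lengths else None
    if not kids:
        return (t.names[node], length)
    return (frozenset(canon_phylo(t, k) for k in kids), length)


class TestRoundTripProperty:
    def test_random_trees_reparse_identically(self, rng):
        for i in range(50):
            t = random_phylotree(rng, int(rng.integers(2, 15)), with_odd_names=(i % 5 == 0))
            s = to_newick(t)
            parsed = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
            assert canon_dendropy(parsed.seed_node) == canon_phylo(t, t.root)


class TestBipartitionLengths:
    def test_basal_bifurcation_edges_merge(self):
        d = bipartition_lengths("((A:1,B:2):3,C:4);")
        assert d[frozenset({"B"})] == 2.0
        # the internal edge and C's edge form the same bipartition {C}|{A,B}
        assert d[frozenset({"C"})] == pytest.approx(7.0)
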