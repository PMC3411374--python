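"""Tree comparison helpers for round-trip evaluation.

Recovered trees are compared with their sources as *unrooted* trees: the
renderer draws a bifurcating root whose two basal branches merge into a
single edge once the image is read back, so rooted comparisons would flag a
spurious difference. Robinson–Foulds distances are computed with dendropy
(an independent, widely used implementation); per-branch length comparison
keys every edge by the tip set on its far side (its bipartition), merging
the two basal edges of a bifurcating root into one with summed length.
"""

from __future__ import annotations

import dendropy
from dendropy.calculate import treecompare

__all__ = ["rf_distance", "bipartition_lengths"]


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson–Foulds (symmetric difference) distance."""
    ns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=ns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=ns)
    ta.is_rooted = False
    tb.is_rooted = False
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(treecompare.symmetric_difference(ta, tb))


def bipartition_lengths(newick: str) -> dict[frozenset, float]:
    """Map each unrooted edge to its length, keyed by a canonical tip set.

    The key is the side of the bipartition that does *not* contain the
    lexicographically smallest taxon, so both trees of a comparison produce
    identical keys regardless of rooting. For a bifurcating root the two
    basal edges carry the same bipartition; their lengths are summed.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = min(all_taxa)
    out: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) == len(all_taxa):
            continue
        key = below if anchor not in below else all_taxa - below
        length = float(node.edge.length or 0.0)
        out[key] = out.get(key, 0.0) + length
    return out
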