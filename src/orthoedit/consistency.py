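"""Species-tree consistency of DS-trees and relation graphs.

A DS-tree is a valid history only if its speciation nodes agree with the
species tree S: under the LCA mapping s_G (each gene-tree node maps to
the lowest species-tree node containing all its leaf species), a
speciation node is consistent iff neither child's mapping is an
(inclusive) ancestor of the other.  A relation graph is S-consistent iff
it is realized by some S-consistent DS-tree.

The graph-level decision works on the canonical cotree: with a binary
species tree, a multifurcating speciation node admits a consistent
binarization iff its children's mappings are pairwise incomparable in S
(partition the children by the child clade of the species tree that
contains their mapping and recurse; conversely, any binarization makes
two comparable mappings meet at some speciation node).  The procedure is
cross-checked in the test suite against an oracle that enumerates every
binary DS-tree on small instances.
"""

from __future__ import annotations

from typing import Optional

from . import cograph
from .model import (
    SPEC,
    DSTree,
    GeneFamily,
    RelationGraph,
    SpeciesTree,
    TreeNode,
    ValidationError,
)


def lca_mapping(
    tree: DSTree, species_tree: SpeciesTree, family: Optional[GeneFamily] = None
) -> dict[int, TreeNode]:
    """The LCA mapping s_G, keyed by ``id`` of the gene-tree node.

    A leaf g maps to the species-tree leaf s(g); an internal node maps to
    the lca in S of the species below it.
    """
    fam = family if family is not None else tree.family
    if fam is None:
        raise ValidationError("a gene family is needed for the LCA mapping")
    mapping: dict[int, TreeNode] = {}
    species_below: dict[int, frozenset[str]] = {}
    for v in tree.root.postorder():
        if v.is_leaf:
            sp = fam.species_of.get(v.label)
            if sp is None:
                raise ValidationError(f"gene {v.label!r} has no species assignment")
            species_below[id(v)] = frozenset([sp])
            mapping[id(v)] = species_tree.leaf(sp)
        else:
            below = frozenset().union(*(species_below[id(c)] for c in v.children))
            species_below[id(v)] = below
            mapping[id(v)] = species_tree.lca(below)
    return mapping


def is_s_consistent_tree(
    tree: DSTree, species_tree: SpeciesTree, family: Optional[GeneFamily] = None
) -> tuple[bool, Optional[TreeNode]]:
    """Check Dup/Spec consistency of a binary DS-tree against S.

    Returns (True, None) if every speciation node maps its two children
    to incomparable species-tree nodes, else (False, first violating node
    in post-order).  Ancestorship is inclusive, so equal mappings violate.
    An all-duplication tree is vacuously consistent.
    """
    mapping = lca_mapping(tree, species_tree, family)
    for v in tree.root.postorder():
        if v.is_leaf or v.event != SPEC:
            continue
        m1, m2 = (mapping[id(c)] for c in v.children)
        if species_tree.comparable(m1, m2):
            return False, v
    return True, None


def is_s_consistent_graph(graph: RelationGraph, species_tree: SpeciesTree) -> bool:
    """Decide whether a relation graph is S-consistent.

    Raises NotSatisfiableError (rather than returning False) when the
    graph is not a cograph; otherwise checks that every series (Spec)
    node of the canonical cotree has pairwise incomparable child
    mappings.
    """
    root = cograph.cotree(graph)  # raises NotSatisfiableError if needed
    fam = graph.family
    species_below: dict[int, frozenset[str]] = {}
    mapping: dict[int, TreeNode] = {}
    for v in root.postorder():
        if v.is_leaf:
            species_below[id(v)] = frozenset([fam.species_of[v.label]])
            mapping[id(v)] = species_tree.leaf(fam.species_of[v.label])
        else:
            species_below[id(v)] = frozenset().union(
                *(species_below[id(c)] for c in v.children)
            )
            mapping[id(v)] = species_tree.lca(species_below[id(v)])
    for v in root.postorder():
        if v.is_leaf or v.event != SPEC:
            continue
        maps = [mapping[id(c)] for c in v.children]
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                if species_tree.comparable(maps[i], maps[j]):
                    return False
    return True


def restrict_species_tree(species_tree: SpeciesTree, species_subset) -> SpeciesTree:
    """The species tree restricted to a subset of its leaves.

    Induced subtree with degree-2 nodes suppressed, rooted at the lca of
    the subset.
    """
    subset = frozenset(species_subset)
    if not subset:
        raise ValidationError("cannot restrict a species tree to an empty set")
    missing = subset - species_tree.species
    if missing:
        raise ValidationError(f"species not in tree: {sorted(missing)}")

    def rec(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            return TreeNode(label=node.label) if node.label in subset else None
        kept = [c for c in (rec(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]  # suppress the degree-2 node
        return TreeNode(children=kept)

    return SpeciesTree(rec(species_tree.root))
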