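"""Satisfiability of relation graphs: cograph (P4-free) recognition,
cotree / DS-tree construction, and the relations induced by a DS-tree.

A relation graph is *satisfiable* — realized by some DS-tree under the
Fitch rule — exactly when it contains no induced path on four vertices
(P4), i.e. when it is a cograph.  Recognition uses the complement-
connectivity dichotomy: a graph is a cograph iff every induced subgraph
on >= 2 vertices is disconnected or has a disconnected complement.  The
recursion directly yields the canonical cotree, whose parallel nodes are
duplications and series nodes speciations.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional

from .model import (
    DUP,
    SPEC,
    DSTree,
    GeneFamily,
    RelationGraph,
    TreeNode,
    ValidationError,
    gene_pair,
)


class NotSatisfiableError(ValidationError):
    """Raised when a P4-free structure is required but absent.

    Carries a witness: four vertices inducing a P4, ordered along the path.
    """

    def __init__(self, witness: tuple[str, str, str, str]):
        self.witness = witness
        super().__init__(
            "relation graph is not satisfiable: vertices "
            f"{witness} induce a P4"
        )


# ---------------------------------------------------------------------------
# Connectivity helpers on induced subgraphs
# ---------------------------------------------------------------------------


def _components(vertices: tuple[str, ...], adj: dict[str, set[str]]) -> list[list[str]]:
    """Connected components of the induced subgraph, each sorted, listed in
    order of their smallest member."""
    vset = set(vertices)
    seen: set[str] = set()
    comps = []
    for start in sorted(vertices):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in adj[v]:
                if u in vset and u not in seen:
                    seen.add(u)
                    stack.append(u)
        comps.append(sorted(comp))
    return comps


def _complement_components(vertices: tuple[str, ...], adj: dict[str, set[str]]) -> list[list[str]]:
    """Components of the complement of the induced subgraph."""
    vset = set(vertices)
    seen: set[str] = set()
    comps = []
    for start in sorted(vertices):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in vset:
                if u is not v and u not in seen and u not in adj[v]:
                    seen.add(u)
                    stack.append(u)
        comps.append(sorted(comp))
    return comps


# ---------------------------------------------------------------------------
# Recognition
# ---------------------------------------------------------------------------


def _cotree_or_witness(graph: RelationGraph, want_witness: bool) -> TreeNode:
    """Build the canonical (multifurcating) cotree by the connectivity
    dichotomy; raise NotSatisfiableError on failure."""
    adj = graph.adjacency()

    def rec(vertices: tuple[str, ...]) -> TreeNode:
        if len(vertices) == 1:
            return TreeNode(label=vertices[0])
        comps = _components(vertices, adj)
        if len(comps) > 1:
            event = DUP
        else:
            comps = _complement_components(vertices, adj)
            if len(comps) > 1:
                event = SPEC
            else:
                witness = find_p4(graph, within=vertices) if want_witness else None
                raise NotSatisfiableError(witness)
        node = TreeNode(event=event)
        for comp in comps:
            node.add_child(rec(tuple(comp)))
        return node

    return rec(tuple(sorted(graph.vertices)))


def is_p4_free(graph: RelationGraph) -> bool:
    """True iff the graph is a cograph (satisfiable)."""
    try:
        _cotree_or_witness(graph, want_witness=False)
    except NotSatisfiableError:
        return False
    return True


def find_p4(
    graph: RelationGraph, within: Optional[tuple[str, ...]] = None
) -> Optional[tuple[str, str, str, str]]:
    """The lexicographically first induced P4, ordered along the path with
    the smaller endpoint first; None if the graph is P4-free.

    Quadruples are scanned as sorted 4-subsets in lexicographic order, so
    the returned witness is deterministic.
    """
    vertices = sorted(within if within is not None else graph.vertices)
    adj = graph.adjacency()
    for quad in combinations(vertices, 4):
        path = _induced_p4_order(quad, adj)
        if path is not None:
            return path
    return None


def _induced_p4_order(
    quad: tuple[str, ...], adj: dict[str, set[str]]
) -> Optional[tuple[str, str, str, str]]:
    """If the four vertices induce a P4, return them in path order with the
    smaller endpoint first; else None."""
    deg = {v: sum(1 for u in quad if u != v and u in adj[v]) for v in quad}
    if sorted(deg.values()) != [1, 1, 2, 2]:
        return None
    ends = sorted(v for v in quad if deg[v] == 1)
    a, d = ends
    if a in adj[d]:  # the two degree-1 vertices adjacent => P3 + K1, not P4
        return None
    (b,) = [v for v in quad if deg[v] == 2 and v in adj[a]]
    (c,) = [v for v in quad if deg[v] == 2 and v in adj[d]]
    if b == c or c not in adj[b]:
        return None
    return (a, b, c, d)


# ---------------------------------------------------------------------------
# Cotree / DS-tree construction
# ---------------------------------------------------------------------------


def cotree(graph: RelationGraph) -> TreeNode:
    """Canonical multifurcating cotree of a satisfiable graph.

    Parallel (disconnected) nodes are labelled Dup, series nodes Spec.
    Children are ordered by their smallest contained gene identifier.
    Raises NotSatisfiableError with a P4 witness otherwise.
    """
    return _cotree_or_witness(graph, want_witness=True)


def _min_leaf(node: TreeNode) -> str:
    return min(node.leaf_labels())


def _binarize(node: TreeNode) -> TreeNode:
    """Binarize multifurcations into left-leaning chains; chain-internal
    nodes inherit the parent's event label (relation-preserving)."""
    if node.is_leaf:
        return TreeNode(label=node.label)
    children = sorted((_binarize(c) for c in node.children), key=_min_leaf)
    acc = children[0]
    for nxt in children[1:]:
        acc = TreeNode(event=node.event, children=[acc, nxt])
    return acc


def build_dstree(graph: RelationGraph) -> DSTree:
    """A binary DS-tree realizing a satisfiable relation graph.

    The cotree recursion emits a Dup node when the induced subgraph is
    disconnected and a Spec node when its complement is; multifurcations
    are binarized relation-preservingly, so
    ``relations_from_dstree(build_dstree(R)) == R``.
    """
    root = _binarize(cotree(graph))
    return DSTree(root=root, family=graph.family)


def dstree_edge_set(tree: DSTree | TreeNode) -> frozenset[tuple[str, str]]:
    """Orthology pairs induced by a DS-tree under the Fitch rule: an edge
    {x, y} iff the event at lca(x, y) is a speciation.

    Works on multifurcating trees too (used for cotrees).
    """
    root = tree.root if isinstance(tree, DSTree) else tree
    edges: set[tuple[str, str]] = set()

    def rec(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.label]
        child_leaves = [rec(c) for c in node.children]
        if node.event == SPEC:
            for i in range(len(child_leaves)):
                for j in range(i + 1, len(child_leaves)):
                    for x in child_leaves[i]:
                        for y in child_leaves[j]:
                            edges.add(gene_pair(x, y))
        return [g for leaves in child_leaves for g in leaves]

    rec(root)
    return frozenset(edges)


def relations_from_dstree(tree: DSTree, family: Optional[GeneFamily] = None) -> RelationGraph:
    """The relation graph induced by a DS-tree (Fitch rule)."""
    fam = family if family is not None else tree.family
    if fam is None:
        raise ValidationError("a gene family is needed to build the relation graph")
    return RelationGraph(fam, dstree_edge_set(tree))


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------


def agreement(graph_a: RelationGraph, graph_b: RelationGraph) -> int:
    """Number of unordered pairs with identical orthology/paralogy status
    in both graphs: |E_a ∩ E_b| + |non-edges in common|.

    This is the objective of the maximization variants of graph
    correction; it equals C(n, 2) minus the symmetric difference size.
    """
    if graph_a.vertices != graph_b.vertices:
        raise ValidationError("agreement requires identical vertex sets")
    n = graph_a.n
    total = n * (n - 1) // 2
    differing = len(graph_a.edges ^ graph_b.edges)
    return total - differing
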