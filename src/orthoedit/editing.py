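"""Greedy min-cut correction of relation graphs.

Both editors exploit the cograph dichotomy: a P4-free graph (or any
induced subgraph of one) is disconnected, or its complement is.  On the
current vertex set Z the algorithm therefore computes a minimum-weight
cut C of R[Z] (edge removals, yielding a duplication node) and a
minimum-weight cut of the complement (non-edge insertions, yielding a
speciation node), applies the cheaper one and recurses on both sides.
Every pair crosses at most one cut, so each pair is edited at most once
and the result is always P4-free.  The total edit weight is at most
n times the optimum.

For species-tree consistency the complement cut is not free: a
speciation must split the genes exactly as the root of the species tree
restricted to their species does.  The consistent editor therefore
forces the complement cut to be that species cut C_S(Z), which makes
every speciation node of the output tree S-consistent by construction,
again within a factor n of the consistent optimum.

Global minimum cuts are delegated to the Stoer-Wagner implementation in
networkx; infinite weights are substituted internally by a finite value
exceeding any finite cut, and true weights are re-derived from the
returned partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import networkx as nx

from . import cograph
from .consistency import restrict_species_tree
from .model import (
    DUP,
    SPEC,
    Cut,
    DSTree,
    EditSet,
    GeneFamily,
    RelationGraph,
    SpeciesTree,
    TreeNode,
    ValidationError,
    WeightTable,
    all_pairs,
    gene_pair,
)


@dataclass(frozen=True)
class GreedyResult:
    """Output of a greedy editor: the edits, their weight beta(R), the
    DS-tree produced by the recursion, and the edited (P4-free) graph."""

    edits: EditSet
    cost: float
    tree: DSTree
    edited_graph: RelationGraph


# ---------------------------------------------------------------------------
# Minimum cuts
# ---------------------------------------------------------------------------


def min_cut_weighted(
    vertex_set: Iterable[str], pair_weights: Mapping[tuple[str, str], float]
) -> Cut:
    """Global minimum-weight cut of the graph whose edges are the pairs in
    *pair_weights* (restricted to *vertex_set*).

    If the positive-weight subgraph is disconnected the cut is free: the
    component containing the lexicographically smallest vertex is split
    off at weight 0 (zero-weight crossing edges are still reported as
    crossing).  Infinite-weight pairs are separated only if every
    bipartition separates one, in which case the cut weight is infinite.
    """
    vertices = sorted(set(vertex_set))
    if len(vertices) < 2:
        raise ValidationError("a cut needs at least two vertices")
    vset = set(vertices)
    edges = {
        gene_pair(a, b): w
        for (a, b), w in pair_weights.items()
        if a in vset and b in vset
    }

    # Disconnected shortcut w.r.t. positive-weight edges.
    adj: dict[str, set[str]] = {v: set() for v in vertices}
    for (a, b), w in edges.items():
        if w > 0:
            adj[a].add(b)
            adj[b].add(a)
    comp = _component_of(vertices[0], adj)
    if len(comp) < len(vertices):
        return _cut_from_sides(comp, vset - comp, edges)

    finite_sum = sum(w for w in edges.values() if not math.isinf(w))
    big = finite_sum + 1.0
    g = nx.Graph()
    g.add_nodes_from(vertices)
    for (a, b), w in sorted(edges.items()):
        if w > 0:
            g.add_edge(a, b, weight=big if math.isinf(w) else w)
    _, (side_a, side_b) = nx.stoer_wagner(g)
    return _cut_from_sides(frozenset(side_a), frozenset(side_b), edges)


def _component_of(start: str, adj: dict[str, set[str]]) -> frozenset[str]:
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return frozenset(seen)


def _cut_from_sides(
    x: frozenset[str], y: frozenset[str], edges: Mapping[tuple[str, str], float]
) -> Cut:
    x, y = frozenset(x), frozenset(y)
    if min(y) < min(x):
        x, y = y, x
    crossing = frozenset(
        p for p in edges if (p[0] in x) != (p[1] in x)
    )
    weight = sum(edges[p] for p in crossing)
    return Cut(x=x, y=y, crossing=crossing, weight=weight)


def species_cut(
    vertex_subset: Iterable[str],
    family: GeneFamily,
    species_tree: SpeciesTree,
) -> Optional[tuple[frozenset[str], frozenset[str]]]:
    """The unique speciation-compatible bipartition of a gene set Z.

    Splits Z by the root bipartition of the species tree restricted to
    the species of Z; None when Z spans a single species (no speciation
    can separate it).  No crossing pair is ever same-species: each
    species lies wholly on one side.
    """
    genes = sorted(set(vertex_subset))
    sigma = {family.species_of[g] for g in genes}
    if len(sigma) < 2:
        return None
    restricted = restrict_species_tree(species_tree, sigma)
    left, right = restricted.root.children
    left_species = restricted.clade(left)
    x = frozenset(g for g in genes if family.species_of[g] in left_species)
    y = frozenset(genes) - x
    if min(y) < min(x):
        x, y = y, x
    return x, y


# ---------------------------------------------------------------------------
# Greedy editors
# ---------------------------------------------------------------------------


def mincut_cograph_editing(
    graph: RelationGraph,
    weights: WeightTable,
    deletion_only: bool = False,
) -> GreedyResult:
    """MinCut-Cograph-Editing: greedy n-approximation of minimum-weight
    editing to satisfiability (deletion-only variant on request).

    At each step the cheaper of the two minimum cuts (on R[Z], giving a
    Dup node, or on its complement, giving a Spec node) is applied; ties
    prefer the cut on R.  With *deletion_only*, complement cuts are never
    taken and the recursion stops early on any Z whose induced subgraph
    is already P4-free, emitting its cotree directly.
    """
    return _greedy(graph, weights, deletion_only=deletion_only, species_tree=None)


def mincut_cograph_editing_cons(
    graph: RelationGraph,
    weights: WeightTable,
    species_tree: SpeciesTree,
) -> GreedyResult:
    """MinCut-Cograph-Editing-Cons: greedy n-approximation of
    minimum-weight editing to S-consistency.

    As the plain editor, but the complement cut is forced to be the
    species cut C_S(Z); when Z spans a single species only the cut on
    R[Z] is considered (R[Z] is then edgeless, so the cut is free).  The
    output tree is S-consistent by construction.
    """
    if species_tree is None:
        raise ValidationError("the consistent editor requires a species tree")
    missing = graph.family.species - species_tree.species
    if missing:
        raise ValidationError(f"species absent from the species tree: {sorted(missing)}")
    return _greedy(graph, weights, deletion_only=False, species_tree=species_tree)


def _greedy(
    graph: RelationGraph,
    weights: WeightTable,
    deletion_only: bool,
    species_tree: Optional[SpeciesTree],
) -> GreedyResult:
    family = graph.family
    edges = set(graph.edges)
    inserted: set[tuple[str, str]] = set()
    removed: set[tuple[str, str]] = set()

    def edge_weights(zset: frozenset[str]) -> dict[tuple[str, str], float]:
        return {
            p: weights[p]
            for p in edges
            if p[0] in zset and p[1] in zset
        }

    def non_edge_weights(zset: frozenset[str]) -> dict[tuple[str, str], float]:
        out = {}
        zs = sorted(zset)
        for i, a in enumerate(zs):
            for b in zs[i + 1:]:
                p = (a, b)
                if p not in edges:
                    out[p] = weights[p]
        return out

    def rec(z: frozenset[str]) -> TreeNode:
        if len(z) == 1:
            (g,) = z
            return TreeNode(label=g)

        if deletion_only:
            sub_family = GeneFamily(
                sorted(z), {g: family.species_of[g] for g in z}
            )
            sub = RelationGraph(
                sub_family,
                {p for p in edges if p[0] in z and p[1] in z},
            )
            if cograph.is_p4_free(sub):
                return cograph.build_dstree(sub).root

        cut_r = min_cut_weighted(z, edge_weights(z))

        cut_comp: Optional[Cut] = None
        if not deletion_only:
            if species_tree is None:
                cut_comp = min_cut_weighted(z, non_edge_weights(z))
            else:
                sides = species_cut(z, family, species_tree)
                if sides is not None:
                    non_edges = non_edge_weights(z)
                    x, y = sides
                    crossing = frozenset(
                        p for p in non_edges if (p[0] in x) != (p[1] in x)
                    )
                    cut_comp = Cut(
                        x=x,
                        y=y,
                        crossing=crossing,
                        weight=sum(non_edges[p] for p in crossing),
                    )

        # Tie-break: prefer the cut on R (a duplication node).
        if cut_comp is None or cut_r.weight <= cut_comp.weight:
            chosen, event = cut_r, DUP
            removed.update(chosen.crossing)
            edges.difference_update(chosen.crossing)
        else:
            chosen, event = cut_comp, SPEC
            inserted.update(chosen.crossing)
            edges.update(chosen.crossing)

        node = TreeNode(event=event)
        node.add_child(rec(chosen.x))
        node.add_child(rec(chosen.y))
        return node

    root = rec(frozenset(graph.vertices))
    edit_set = EditSet(inserted, removed, weights.total(inserted | removed))
    tree = DSTree(root=root, family=family)
    edited = RelationGraph(family, edges)
    return GreedyResult(edits=edit_set, cost=edit_set.total_weight, tree=tree,
                        edited_graph=edited)


# ---------------------------------------------------------------------------
# Agreement baseline
# ---------------------------------------------------------------------------


def baseline_agreement(
    graph: RelationGraph, species_tree: Optional[SpeciesTree] = None
) -> tuple[RelationGraph, DSTree, int]:
    """The half-agreement baseline for the maximization variants.

    Evaluates two trivially feasible solutions: R' with no orthologies at
    all, and R'' where all genes from distinct species are orthologs (a
    complete multipartite graph with parts the species classes).  Every
    pair agrees with R in exactly one of the two, so the better one has
    agreement >= ceil(C(n,2) / 2).  Returns that solution (ties favour
    R'), a witnessing DS-tree, and the agreement value.  With a species
    tree, the R'' witness follows the species-tree topology and is
    therefore S-consistent.
    """
    family = graph.family
    genes = sorted(family.genes)
    n = len(genes)

    edgeless = RelationGraph(family, frozenset())
    multipartite_edges = frozenset(
        p for p in all_pairs(genes) if not family.same_species(*p)
    )
    multipartite = RelationGraph(family, multipartite_edges)

    a_prime = cograph.agreement(graph, edgeless)
    a_second = cograph.agreement(graph, multipartite)

    if a_prime >= a_second:
        tree = _dup_chain_tree(genes, family)
        return edgeless, tree, a_prime
    tree = _multipartite_tree(family, species_tree)
    return multipartite, tree, a_second


def _chain(nodes: list[TreeNode], event: str) -> TreeNode:
    acc = nodes[0]
    for nxt in nodes[1:]:
        acc = TreeNode(event=event, children=[acc, nxt])
    return acc


def _dup_chain_tree(genes: list[str], family: GeneFamily) -> DSTree:
    if len(genes) == 1:
        return DSTree(root=TreeNode(label=genes[0]), family=family)
    return DSTree(root=_chain([TreeNode(label=g) for g in genes], DUP), family=family)


def _multipartite_tree(family: GeneFamily, species_tree: Optional[SpeciesTree]) -> DSTree:
    by_species: dict[str, list[str]] = {}
    for g in sorted(family.genes):
        by_species.setdefault(family.species_of[g], []).append(g)

    def species_subtree(sp: str) -> TreeNode:
        return _chain([TreeNode(label=g) for g in by_species[sp]], DUP)

    if species_tree is not None:
        restricted = restrict_species_tree(species_tree, by_species.keys())

        def follow(node: TreeNode) -> TreeNode:
            if node.is_leaf:
                return species_subtree(node.label)
            out = TreeNode(event=SPEC)
            for c in node.children:
                out.add_child(follow(c))
            return out

        root = follow(restricted.root)
    else:
        parts = [species_subtree(sp) for sp in sorted(by_species)]
        root = _chain(parts, SPEC) if len(parts) > 1 else parts[0]
    return DSTree(root=root, family=family)
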