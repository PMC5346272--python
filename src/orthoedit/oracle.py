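"""Exhaustive exact solvers, used as ground truth for the greedy editors.

These are deliberately independent of the production code paths: P4
detection here enumerates 4-subsets with bitset adjacency instead of the
connectivity recursion, minimum cuts enumerate every bipartition, and
the editing optima enumerate edit subsets ordered by cardinality and
then lexicographically, with weight-based pruning.  Hard size guards
keep them honest (they are test oracles, not production solvers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Iterator, Mapping, Optional

from .consistency import is_s_consistent_graph
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

MAX_EDIT_VERTICES = 7
MAX_CONS_VERTICES = 6
MAX_CUT_VERTICES = 12
MAX_TREE_GENES = 5


@dataclass(frozen=True)
class OracleResult:
    """Exact optimum: sigma_R and the first optimal edit set in
    cardinality-then-lexicographic subset order."""

    optimum_weight: float
    argmin: EditSet


class OracleSizeError(ValidationError):
    """Input exceeds the exhaustive-search size guard."""


# ---------------------------------------------------------------------------
# Bitset P4 test (independent of the cograph-module recursion)
# ---------------------------------------------------------------------------


def _adjacency_masks(n: int, edge_indices: Iterable[tuple[int, int]]) -> list[int]:
    masks = [0] * n
    for i, j in edge_indices:
        masks[i] |= 1 << j
        masks[j] |= 1 << i
    return masks


def _p4_free_masks(n: int, masks: list[int]) -> bool:
    for quad in combinations(range(n), 4):
        degs = []
        qmask = 0
        for v in quad:
            qmask |= 1 << v
        edge_count = 0
        for v in quad:
            d = bin(masks[v] & qmask).count("1")
            degs.append(d)
            edge_count += d
        if edge_count != 6:  # 2 * 3 edges
            continue
        if sorted(degs) != [1, 1, 2, 2]:
            continue
        ends = [v for v in quad if bin(masks[v] & qmask).count("1") == 1]
        if not (masks[ends[0]] >> ends[1]) & 1:
            return False
    return True


def is_p4_free_bruteforce(graph: RelationGraph) -> bool:
    """P4-freeness by enumeration of all 4-subsets."""
    verts = sorted(graph.vertices)
    index = {v: i for i, v in enumerate(verts)}
    masks = _adjacency_masks(
        len(verts), ((index[a], index[b]) for a, b in graph.edges)
    )
    return _p4_free_masks(len(verts), masks)


def find_p4_bruteforce(graph: RelationGraph) -> Optional[tuple[str, str, str, str]]:
    """Lexicographically first induced P4 by 4-subset enumeration."""
    verts = sorted(graph.vertices)
    adj = graph.adjacency()
    for quad in combinations(verts, 4):
        deg = {v: sum(1 for u in quad if u != v and u in adj[v]) for v in quad}
        if sorted(deg.values()) != [1, 1, 2, 2]:
            continue
        a, d = sorted(v for v in quad if deg[v] == 1)
        if a in adj[d]:
            continue
        b = next(v for v in quad if deg[v] == 2 and v in adj[a])
        c = next(v for v in quad if deg[v] == 2 and v in adj[d])
        if b != c and c in adj[b]:
            return (a, b, c, d)
    return None


# ---------------------------------------------------------------------------
# Exact editing optima
# ---------------------------------------------------------------------------


def brute_force_edit(
    graph: RelationGraph,
    weights: WeightTable,
    deletion_only: bool = False,
    max_vertices: int = MAX_EDIT_VERTICES,
) -> OracleResult:
    """Minimum-weight P4-free edge-editing by subset enumeration.

    Editable pairs are all non-same-species pairs (current edges only,
    with *deletion_only*).  Subsets are scanned by increasing cardinality
    and then lexicographically over the sorted pair list; a subset is
    skipped once its weight reaches the incumbent, and whole cardinality
    levels are skipped once the sum of the k cheapest pair weights does.
    The reported argmin is the first optimum in that order.
    """
    if graph.n > max_vertices:
        raise OracleSizeError(
            f"brute-force editing limited to {max_vertices} vertices, got {graph.n}"
        )

    def feasible(edge_set: frozenset[tuple[str, str]]) -> bool:
        verts = sorted(graph.vertices)
        index = {v: i for i, v in enumerate(verts)}
        masks = _adjacency_masks(
            len(verts), ((index[a], index[b]) for a, b in edge_set)
        )
        return _p4_free_masks(len(verts), masks)

    return _enumerate_edits(graph, weights, deletion_only, feasible)


def brute_force_edit_cons(
    graph: RelationGraph,
    weights: WeightTable,
    species_tree: SpeciesTree,
    max_vertices: int = MAX_CONS_VERTICES,
) -> OracleResult:
    """Minimum-weight S-consistent edge-editing by subset enumeration."""
    if graph.n > max_vertices:
        raise OracleSizeError(
            f"brute-force consistent editing limited to {max_vertices} vertices, "
            f"got {graph.n}"
        )

    def feasible(edge_set: frozenset[tuple[str, str]]) -> bool:
        candidate = RelationGraph(graph.family, edge_set)
        try:
            return is_s_consistent_graph(candidate, species_tree)
        except ValidationError:
            return False

    return _enumerate_edits(graph, weights, False, feasible)


def _enumerate_edits(graph, weights, deletion_only, feasible) -> OracleResult:
    family = graph.family
    if deletion_only:
        editable = sorted(graph.edges)
    else:
        editable = sorted(
            p for p in all_pairs(family.genes) if not family.same_species(*p)
        )
    pair_w = [weights[p] for p in editable]
    m = len(editable)

    def edited_edges(subset: tuple[int, ...]) -> frozenset[tuple[str, str]]:
        edge_set = set(graph.edges)
        for i in subset:
            p = editable[i]
            if p in edge_set:
                edge_set.discard(p)
            else:
                edge_set.add(p)
        return frozenset(edge_set)

    # Seed the incumbent with the remove-everything solution (always
    # feasible: the edgeless graph is a cograph and vacuously consistent)
    # so the cardinality lower bound can terminate the enumeration early.
    best_w = math.inf
    best_subset: Optional[tuple[int, ...]] = None
    best_is_enumerated = False
    seed = tuple(i for i, p in enumerate(editable) if p in graph.edges)
    if feasible(edited_edges(seed)):
        best_w = sum(pair_w[i] for i in seed)
        best_subset = seed

    # prefix[k] = sum of the k cheapest editable weights, a lower bound on
    # the weight of any cardinality-k subset.
    prefix = [0.0]
    for w in sorted(pair_w):
        prefix.append(prefix[-1] + w)

    for k in range(0, m + 1):
        if prefix[k] > best_w or (prefix[k] == best_w and best_is_enumerated):
            break
        for subset in combinations(range(m), k):
            w = sum(pair_w[i] for i in subset)
            if w > best_w or (w == best_w and best_is_enumerated):
                continue
            if feasible(edited_edges(subset)):
                best_w = w
                best_subset = subset
                best_is_enumerated = True

    if best_subset is None:  # pragma: no cover - defensive
        raise ValidationError("no feasible editing found")
    removed = frozenset(editable[i] for i in best_subset if editable[i] in graph.edges)
    inserted = frozenset(
        editable[i] for i in best_subset if editable[i] not in graph.edges
    )
    edits = EditSet(inserted, removed, best_w)
    return OracleResult(optimum_weight=best_w, argmin=edits)


# ---------------------------------------------------------------------------
# Exact minimum cut
# ---------------------------------------------------------------------------


def brute_force_min_cut(
    vertex_set: Iterable[str], pair_weights: Mapping[tuple[str, str], float]
) -> Cut:
    """Global minimum cut by enumeration of all 2^(n-1) - 1 bipartitions."""
    vertices = sorted(set(vertex_set))
    n = len(vertices)
    if n < 2 or n > MAX_CUT_VERTICES:
        raise OracleSizeError(f"brute-force min cut needs 2..{MAX_CUT_VERTICES} vertices")
    edges = {
        gene_pair(a, b): w
        for (a, b), w in pair_weights.items()
        if a in set(vertices) and b in set(vertices)
    }
    best: Optional[Cut] = None
    # Fix vertices[0] on side X to halve the enumeration.
    rest = vertices[1:]
    for bits in range(2 ** (n - 1)):
        x = {vertices[0]}
        for i, v in enumerate(rest):
            if not (bits >> i) & 1:
                x.add(v)
        if len(x) == n:
            continue
        y = frozenset(vertices) - x
        crossing = frozenset(p for p in edges if (p[0] in x) != (p[1] in x))
        w = sum(edges[p] for p in crossing)
        if best is None or w < best.weight:
            best = Cut(x=frozenset(x), y=y, crossing=crossing, weight=w)
    return best


# ---------------------------------------------------------------------------
# DS-tree enumeration
# ---------------------------------------------------------------------------


def enumerate_ds_trees(
    genes: Iterable[str], family: Optional[GeneFamily] = None
) -> Iterator[DSTree]:
    """Every binary DS-tree on the gene set: all rooted binary labelled
    topologies times all Dup/Spec labelings, each exactly once."""
    genes = sorted(set(genes))
    if len(genes) > MAX_TREE_GENES:
        raise OracleSizeError(
            f"DS-tree enumeration limited to {MAX_TREE_GENES} genes, got {len(genes)}"
        )

    def topologies(leafset: tuple[str, ...]) -> Iterator[TreeNode]:
        if len(leafset) == 1:
            yield TreeNode(label=leafset[0])
            return
        first, rest = leafset[0], leafset[1:]
        # The subtree containing the first leaf determines the root split
        # uniquely, so every topology is produced exactly once.
        for r in range(len(rest)):
            for others in combinations(rest, r):
                left = (first,) + others
                right = tuple(g for g in rest if g not in others)
                if not right:
                    continue
                for lt in topologies(left):
                    for rt in topologies(right):
                        root = TreeNode(children=[_copy(lt), _copy(rt)])
                        yield root

    def _copy(node: TreeNode) -> TreeNode:
        if node.is_leaf:
            return TreeNode(label=node.label)
        return TreeNode(event=node.event,
                        children=[_copy(c) for c in node.children])

    for topo in topologies(tuple(genes)):
        internals = [v for v in topo.postorder() if not v.is_leaf]
        for labels in product((DUP, SPEC), repeat=len(internals)):
            for v, ev in zip(internals, labels):
                v.event = ev
            yield DSTree(root=_copy(topo), family=family)
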