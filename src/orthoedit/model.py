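"""Core domain types for orthology/paralogy relation graphs.

A gene family is a set of genes, each belonging to one species.  The
pairwise orthology/paralogy relations over the family form a *relation
graph*: vertices are genes, edges are orthologies, non-edges (missing
edges) are paralogies.  Two genes from the same species are necessarily
paralogs, so a same-species pair is a *forced* non-edge and carries
infinite edit weight.

Everything downstream (cograph recognition, DS-tree building, consistency
checking, the greedy editors, the exhaustive oracles) works on the types
defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Mapping, Optional

#: Event label for duplication nodes of a DS-tree.
DUP = "D"
#: Event label for speciation nodes of a DS-tree.
SPEC = "S"

#: Weight of a forced paralogy (same-species pair).  Public contract:
#: infinity is represented by ``math.inf``, never a numeric sentinel.
INFINITE_WEIGHT = math.inf

#: Default weight assigned to pairs absent from an explicit weight table.
#: With all weights 1 the weighted problems reduce to the unweighted ones.
DEFAULT_WEIGHT = 1.0


class ValidationError(ValueError):
    """An instance violates a structural invariant."""


def gene_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographically ordered) form of an unordered pair."""
    if a == b:
        raise ValidationError(f"self-pair {a!r} is not a valid gene pair")
    return (a, b) if a < b else (b, a)


def all_pairs(genes: Iterable[str]) -> Iterator[tuple[str, str]]:
    """All canonical unordered pairs over *genes*, in lexicographic order."""
    return combinations(sorted(genes), 2)


# ---------------------------------------------------------------------------
# Gene families and relation graphs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFamily:
    """A gene family: gene identifiers plus the gene -> species map ``s``."""

    genes: tuple[str, ...]
    species_of: Mapping[str, str]

    def __init__(self, genes: Iterable[str], species_of: Mapping[str, str]):
        genes = tuple(sorted(genes))
        if len(set(genes)) != len(genes):
            raise ValidationError("duplicate gene identifiers")
        for g in genes:
            if not g:
                raise ValidationError("empty gene identifier")
            if g not in species_of:
                raise ValidationError(f"gene {g!r} has no species assignment")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "species_of", dict(species_of))

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.species_of[g] for g in self.genes)

    def same_species(self, a: str, b: str) -> bool:
        return self.species_of[a] == self.species_of[b]


@dataclass(frozen=True)
class RelationGraph:
    """Relation graph on a gene family: edges = orthologies.

    Non-edges are paralogies.  An edge between two genes of the same
    species would violate forced paralogy and is rejected.
    """

    family: GeneFamily
    edges: frozenset[tuple[str, str]]

    def __init__(self, family: GeneFamily, edges: Iterable[tuple[str, str]]):
        known = set(family.genes)
        canon = set()
        for a, b in edges:
            if a not in known or b not in known:
                raise ValidationError(f"edge endpoint not in family: {{{a!r}, {b!r}}}")
            p = gene_pair(a, b)
            if family.same_species(*p):
                raise ValidationError(
                    f"forced paralogy violated: {p[0]!r} and {p[1]!r} are from "
                    f"species {family.species_of[p[0]]!r} but listed as orthologs"
                )
            canon.add(p)
        object.__setattr__(self, "family", family)
        object.__setattr__(self, "edges", frozenset(canon))

    @property
    def n(self) -> int:
        return self.family.n

    @property
    def vertices(self) -> tuple[str, ...]:
        return self.family.genes

    def has_edge(self, a: str, b: str) -> bool:
        return gene_pair(a, b) in self.edges

    def non_edges(self) -> Iterator[tuple[str, str]]:
        """All non-edges (paralogies), including forced same-species pairs."""
        for p in all_pairs(self.vertices):
            if p not in self.edges:
                yield p

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.vertices}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def complement_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.non_edges())

    def __eq__(self, other) -> bool:  # same relations on the same gene set
        if not isinstance(other, RelationGraph):
            return NotImplemented
        return self.vertices == other.vertices and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.vertices, self.edges))


@dataclass(frozen=True)
class WeightTable:
    """Total weight function ``w`` on unordered gene pairs.

    Defined on every pair (edges and non-edges).  Same-species pairs are
    forced to ``INFINITE_WEIGHT``.  Weights may be 0; optimal solutions
    are then not necessarily unique.
    """

    weights: Mapping[tuple[str, str], float]

    def __init__(self, weights: Mapping[tuple[str, str], float]):
        object.__setattr__(self, "weights", dict(weights))

    @classmethod
    def complete(
        cls,
        family: GeneFamily,
        weights: Optional[Mapping[tuple[str, str], float]] = None,
        default: float = DEFAULT_WEIGHT,
    ) -> "WeightTable":
        """Fill in a total table: listed weights, *default* elsewhere,
        infinity on same-species pairs regardless of input."""
        given = {}
        if weights:
            for (a, b), w in weights.items():
                if w < 0:
                    raise ValidationError(f"negative weight on pair ({a!r}, {b!r})")
                given[gene_pair(a, b)] = float(w)
        table = {}
        for p in all_pairs(family.genes):
            if family.same_species(*p):
                table[p] = INFINITE_WEIGHT
            else:
                table[p] = given.get(p, default)
        return cls(table)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self.weights[gene_pair(*pair)]

    def total(self, pairs: Iterable[tuple[str, str]]) -> float:
        """Extension of ``w`` to a pair set: sum of member weights."""
        return sum(self[p] for p in pairs)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class TreeNode:
    """A node of a rooted tree; leaves carry labels, internal nodes may
    carry an event label (``DUP``/``SPEC``) when part of a DS-tree."""

    __slots__ = ("label", "event", "children", "parent")

    def __init__(self, label: Optional[str] = None, event: Optional[str] = None,
                 children: Optional[list["TreeNode"]] = None):
        self.label = label
        self.event = event
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        for c in children or []:
            self.add_child(c)

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaves(self) -> list["TreeNode"]:
        return [v for v in self.postorder() if v.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [v.label for v in self.leaves()]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Leaf({self.label})"
        return f"Node({self.event}, {len(self.children)} children)"


class SpeciesTree:
    """A rooted binary species tree with leaves labelled by species.

    Supports lca queries over species subsets and inclusive ancestor
    tests (a node is an ancestor of itself).
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._clade: dict[int, frozenset[str]] = {}
        labels = []
        for v in root.postorder():
            if v.is_leaf:
                if not v.label:
                    raise ValidationError("species tree leaf without a label")
                labels.append(v.label)
                self._clade[id(v)] = frozenset([v.label])
            else:
                if len(v.children) != 2:
                    raise ValidationError("species tree must be binary")
                self._clade[id(v)] = frozenset().union(
                    *(self._clade[id(c)] for c in v.children)
                )
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate species labels in species tree")
        self._leaf_by_label = {v.label: v for v in root.leaves()}

    @property
    def species(self) -> frozenset[str]:
        return self._clade[id(self.root)]

    def clade(self, node: TreeNode) -> frozenset[str]:
        return self._clade[id(node)]

    def leaf(self, label: str) -> TreeNode:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise ValidationError(f"species {label!r} not in species tree") from None

    def lca(self, labels: Iterable[str]) -> TreeNode:
        """Lowest node whose clade contains every label in *labels*."""
        want = frozenset(labels)
        missing = want - self.species
        if missing:
            raise ValidationError(f"species not in tree: {sorted(missing)}")
        node = self.root
        while not node.is_leaf:
            for c in node.children:
                if want <= self._clade[id(c)]:
                    node = c
                    break
            else:
                return node
        return node

    def is_ancestor(self, u: TreeNode, v: TreeNode) -> bool:
        """Inclusive ancestorship: u is on the path from v to the root."""
        while v is not None:
            if v is u:
                return True
            v = v.parent
        return False

    def comparable(self, u: TreeNode, v: TreeNode) -> bool:
        return self.is_ancestor(u, v) or self.is_ancestor(v, u)


@dataclass
class DSTree:
    """A rooted binary gene tree with Dup/Spec labels on internal nodes.

    Leaves are in bijection with the gene family.  Internal nodes model
    duplication or speciation events; the Fitch rule reads orthology off
    the tree (two genes are orthologs iff their lca is a speciation).
    """

    root: TreeNode
    family: Optional[GeneFamily] = None

    def __post_init__(self):
        for v in self.root.postorder():
            if v.is_leaf:
                if not v.label:
                    raise ValidationError("DS-tree leaf without a gene label")
            else:
                if len(v.children) != 2:
                    raise ValidationError("DS-tree must be binary")
                if v.event not in (DUP, SPEC):
                    raise ValidationError(
                        f"internal DS-tree node lacks a Dup/Spec label: {v.event!r}"
                    )
        genes = self.root.leaf_labels()
        if len(set(genes)) != len(genes):
            raise ValidationError("duplicate gene labels in DS-tree")
        if self.family is not None and set(genes) != set(self.family.genes):
            raise ValidationError("DS-tree leaves do not match the gene family")

    @property
    def genes(self) -> list[str]:
        return self.root.leaf_labels()


# ---------------------------------------------------------------------------
# Edits and cuts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EditSet:
    """An edge-editing: inserted non-edges E+ and removed edges E-."""

    inserted: frozenset[tuple[str, str]]
    removed: frozenset[tuple[str, str]]
    total_weight: float

    def __init__(self, inserted: Iterable[tuple[str, str]],
                 removed: Iterable[tuple[str, str]],
                 total_weight: float):
        ins = frozenset(gene_pair(*p) for p in inserted)
        rem = frozenset(gene_pair(*p) for p in removed)
        if ins & rem:
            raise ValidationError("inserted and removed pair sets overlap")
        object.__setattr__(self, "inserted", ins)
        object.__setattr__(self, "removed", rem)
        object.__setattr__(self, "total_weight", float(total_weight))

    @property
    def size(self) -> int:
        return len(self.inserted) + len(self.removed)

    def apply(self, graph: RelationGraph) -> RelationGraph:
        if not self.inserted <= frozenset(graph.non_edges()):
            raise ValidationError("inserted pairs must be non-edges of the input")
        if not self.removed <= graph.edges:
            raise ValidationError("removed pairs must be edges of the input")
        return RelationGraph(graph.family, (graph.edges | self.inserted) - self.removed)


EMPTY_EDITS = EditSet(frozenset(), frozenset(), 0.0)


@dataclass(frozen=True)
class Cut:
    """A bipartition {X, Y} of a vertex set, with the crossing pairs that
    must be edited and their total weight."""

    x: frozenset[str]
    y: frozenset[str]
    crossing: frozenset[tuple[str, str]]
    weight: float

    def __post_init__(self):
        if not self.x or not self.y:
            raise ValidationError("both sides of a cut must be non-empty")
        if self.x & self.y:
            raise ValidationError("cut sides must be disjoint")


# ---------------------------------------------------------------------------
# Instance validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Instance:
    family: GeneFamily
    graph: RelationGraph
    weights: WeightTable
    species_tree: Optional[SpeciesTree] = None


def validate_instance(
    family: GeneFamily,
    graph: RelationGraph,
    weights: Optional[WeightTable | Mapping[tuple[str, str], float]] = None,
    species_tree: Optional[SpeciesTree] = None,
) -> Instance:
    """Check all invariants and return a validated instance.

    Pairs absent from the weight table get ``DEFAULT_WEIGHT``; same-species
    pairs are forced to infinite weight.  With a species tree, every
    species of the gene map must occur as a leaf.
    """
    if graph.family is not family and graph.family != family:
        raise ValidationError("relation graph is not over the given family")
    if isinstance(weights, WeightTable):
        table = WeightTable.complete(family, weights.weights)
    else:
        table = WeightTable.complete(family, weights)
    for p in all_pairs(family.genes):
        w = table[p]
        if w < 0:
            raise ValidationError(f"negative weight on pair {p}")
        if family.same_species(*p) and not math.isinf(w):
            raise ValidationError(f"same-species pair {p} must have infinite weight")
    if species_tree is not None:
        missing = family.species - species_tree.species
        if missing:
            raise ValidationError(
                f"species in the gene map absent from the species tree: {sorted(missing)}"
            )
    return Instance(family, graph, table, species_tree)
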