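"""Seeded generators for every instance family the tests exercise.

All generators are pure functions of their arguments (seed included):
the same call produces byte-identical output.  Random cographs are drawn
by sampling a random DS-tree and reading its relations off, so they are
satisfiable by construction; perturbed cographs ship with their flip set,
which upper-bounds the unit-weight editing optimum by k.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from . import cograph
from .model import (
    DUP,
    SPEC,
    DSTree,
    GeneFamily,
    RelationGraph,
    SpeciesTree,
    TreeNode,
    ValidationError,
    WeightTable,
    all_pairs,
)
from .hardness import MulticutInstance


@dataclass(frozen=True)
class SynthConfig:
    """Reproducible description of a generated instance."""

    seed: int
    n_genes: int = 8
    n_species: int = 4
    perturbation_count: int = 0
    family: str = "random_cograph"


# ---------------------------------------------------------------------------
# Species trees and gene families
# ---------------------------------------------------------------------------


def _random_binary_tree(labels: list[str], rng: random.Random) -> TreeNode:
    """Random rooted binary topology by sequential random joins."""
    nodes = [TreeNode(label=x) for x in labels]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(TreeNode(children=[a, b]))
    return nodes[0]


def random_species_instance(
    n_species: int, n_genes: int, seed: int
) -> tuple[GeneFamily, SpeciesTree]:
    """A random binary species tree plus genes assigned to its species.

    Species are named s01, s02, ...; genes g01, g02, ....  When there are
    at least as many genes as species, every species receives at least
    one gene (round-robin base assignment, random for the remainder).
    """
    if n_species < 1:
        raise ValidationError("need at least one species")
    if n_genes < 1:
        raise ValidationError("need at least one gene")
    rng = random.Random(seed)
    species = [f"s{i:02d}" for i in range(1, n_species + 1)]
    tree = SpeciesTree(_random_binary_tree(species, rng))
    genes = [f"g{i:02d}" for i in range(1, n_genes + 1)]
    assignment = {}
    for i, g in enumerate(genes):
        if i < n_species and n_genes >= n_species:
            assignment[g] = species[i]
        else:
            assignment[g] = rng.choice(species)
    return GeneFamily(genes, assignment), tree


# ---------------------------------------------------------------------------
# Cographs and perturbations
# ---------------------------------------------------------------------------


def random_dstree(family: GeneFamily, seed: int) -> DSTree:
    """A random binary DS-tree over the family.

    Labels are Dup/Spec with probability 1/2, except that any node whose
    two child clades share a species is forced to Dup — a speciation
    there would make two same-species genes orthologs.
    """
    rng = random.Random(seed)
    root = _random_binary_tree(list(family.genes), rng)
    species_below: dict[int, frozenset[str]] = {}
    for v in root.postorder():
        if v.is_leaf:
            species_below[id(v)] = frozenset([family.species_of[v.label]])
        else:
            left, right = (species_below[id(c)] for c in v.children)
            species_below[id(v)] = left | right
            if left & right:
                v.event = DUP
            else:
                v.event = SPEC if rng.random() < 0.5 else DUP
    return DSTree(root=root, family=family)


def random_cograph(family: GeneFamily, seed: int) -> RelationGraph:
    """A random satisfiable relation graph: relations of a random DS-tree."""
    return cograph.relations_from_dstree(random_dstree(family, seed))


def random_graph(family: GeneFamily, edge_prob: float, seed: int) -> RelationGraph:
    """Erdos-Renyi-style relation graph; same-species pairs stay non-edges."""
    rng = random.Random(seed)
    edges = [
        p
        for p in all_pairs(family.genes)
        if not family.same_species(*p) and rng.random() < edge_prob
    ]
    return RelationGraph(family, edges)


def perturb_graph(
    graph: RelationGraph, k: int, seed: int
) -> tuple[RelationGraph, frozenset[tuple[str, str]]]:
    """Flip k distinct non-forced pairs; returns the graph and the flip set.

    Under unit weights the editing optimum of the result is at most k
    (flipping them back restores the input).
    """
    family = graph.family
    candidates = [p for p in all_pairs(family.genes) if not family.same_species(*p)]
    if k > len(candidates):
        raise ValidationError(f"cannot flip {k} of {len(candidates)} editable pairs")
    rng = random.Random(seed)
    flips = frozenset(rng.sample(candidates, k))
    edges = set(graph.edges)
    for p in flips:
        if p in edges:
            edges.discard(p)
        else:
            edges.add(p)
    return RelationGraph(family, edges), flips


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------


def unit_weights(family: GeneFamily) -> WeightTable:
    return WeightTable.complete(family)


def random_weights(
    family: GeneFamily, seed: int, distribution: str = "exponential"
) -> WeightTable:
    """Random positive pair weights: 'exponential' (mean 1) or 'uniform'
    on (0, 2).  No claim of biological realism; these exercise the
    weighted code paths."""
    rng = random.Random(seed)
    if distribution == "exponential":
        draw = lambda: rng.expovariate(1.0)
    elif distribution == "uniform":
        draw = lambda: rng.uniform(0.0, 2.0)
    else:
        raise ValidationError(f"unknown weight distribution {distribution!r}")
    table = {
        p: draw()
        for p in all_pairs(family.genes)
        if not family.same_species(*p)
    }
    return WeightTable.complete(family, table)


# ---------------------------------------------------------------------------
# Named instance families
# ---------------------------------------------------------------------------


def double_star(n: int) -> tuple[RelationGraph, WeightTable]:
    """The tightness instance for the greedy editor: two adjacent centers,
    each with (n-2)/2 pendant leaves, unit weights, one species per gene.

    The optimum removes the single center-center edge (weight 1), while a
    minimum cut may peel off pendant leaves one at a time; with odd n the
    left center receives the extra leaf.
    """
    if n < 6:
        raise ValidationError("double star needs at least 6 vertices")
    n_left = (n - 2 + 1) // 2
    n_right = n - 2 - n_left
    genes = ["u0", "v0"]
    edges = [("u0", "v0")]
    for i in range(1, n_left + 1):
        leaf = f"l{i}"
        genes.append(leaf)
        edges.append(("u0", leaf))
    for i in range(1, n_right + 1):
        leaf = f"r{i}"
        genes.append(leaf)
        edges.append(("v0", leaf))
    family = GeneFamily(genes, {g: f"sp_{g}" for g in genes})
    graph = RelationGraph(family, edges)
    return graph, WeightTable.complete(family)


def random_multicut_instance(
    n_vertices: int,
    edge_prob: float,
    n_terminal_pairs: int,
    seed: int,
) -> MulticutInstance:
    """A random Minimum Multi-Cut instance (Erdos-Renyi edges, terminal
    pairs sampled without replacement)."""
    if n_vertices < 2:
        raise ValidationError("multicut instance needs at least two vertices")
    rng = random.Random(seed)
    vertices = [f"v{i:02d}" for i in range(1, n_vertices + 1)]
    pairs = list(all_pairs(vertices))
    edges = [p for p in pairs if rng.random() < edge_prob]
    if n_terminal_pairs > len(pairs):
        raise ValidationError(
            f"cannot sample {n_terminal_pairs} terminal pairs from {len(pairs)}"
        )
    terminals = rng.sample(pairs, n_terminal_pairs)
    return MulticutInstance(vertices, edges, terminals)
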