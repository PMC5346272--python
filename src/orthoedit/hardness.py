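"""The minimum-multicut gadget: adversarial weighted instances.

Minimum Multi-Cut (given a graph H and terminal pairs X, delete the
fewest edges so that every pair in X is disconnected) translates into
weighted cograph deletion on a relation graph that doubles every vertex
of H.  The two copies v_i and v'_i are tied by a heavy "spine" edge; a
terminal pair gets a direct edge between primary copies (weight q if it
is an H-edge, 1 otherwise), and a non-terminal pair gets the two cross
edges between primary and shadow copies (weight q/2 each if an H-edge,
1 otherwise).  Non-edges carry the spine weight so insertions are never
profitable.  With q polynomially larger than any multicut, optimal
editings of the gadget and optimal multicuts of (H, X) translate into
one another, which is what makes constant-factor approximation of the
weighted editing problems unlikely.

This module implements the two constructive translations (multicut ->
editing, editing -> multicut) so the correspondence can be verified
exhaustively on small instances; the asymptotic argument itself is not
code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

from .model import (
    EditSet,
    GeneFamily,
    RelationGraph,
    ValidationError,
    WeightTable,
    gene_pair,
)


@dataclass(frozen=True)
class MulticutInstance:
    """A Minimum Multi-Cut instance: graph H, terminal pairs X, and
    optionally a candidate solution (edge set disconnecting every pair)."""

    vertices: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    terminal_pairs: frozenset[tuple[str, str]]
    solution: Optional[frozenset[tuple[str, str]]] = None

    def __init__(self, vertices, edges, terminal_pairs, solution=None):
        vertices = tuple(sorted(set(vertices)))
        vset = set(vertices)
        canon_edges = set()
        for a, b in edges:
            if a not in vset or b not in vset:
                raise ValidationError(f"edge endpoint not a vertex: {{{a!r}, {b!r}}}")
            canon_edges.add(gene_pair(a, b))
        canon_x = set()
        for a, b in terminal_pairs:
            if a not in vset or b not in vset:
                raise ValidationError(f"terminal not a vertex: {{{a!r}, {b!r}}}")
            canon_x.add(gene_pair(a, b))
        canon_sol = None
        if solution is not None:
            canon_sol = frozenset(gene_pair(a, b) for a, b in solution)
            if not canon_sol <= frozenset(canon_edges):
                raise ValidationError("solution must be a subset of the edges")
        object.__setattr__(self, "vertices", vertices)
        object.__setattr__(self, "edges", frozenset(canon_edges))
        object.__setattr__(self, "terminal_pairs", frozenset(canon_x))
        object.__setattr__(self, "solution", canon_sol)

    def components_after(self, removed: frozenset[tuple[str, str]]) -> list[frozenset[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.vertices}
        for a, b in self.edges - removed:
            adj[a].add(b)
            adj[b].add(a)
        seen: set[str] = set()
        comps = []
        for start in self.vertices:
            if start in seen:
                continue
            stack, comp = [start], set()
            seen.add(start)
            while stack:
                v = stack.pop()
                comp.add(v)
                for u in adj[v]:
                    if u not in seen:
                        seen.add(u)
                        stack.append(u)
            comps.append(frozenset(comp))
        return comps

    def is_multicut(self, removed: frozenset[tuple[str, str]]) -> bool:
        comps = self.components_after(removed)
        where = {v: i for i, comp in enumerate(comps) for v in comp}
        return all(where[a] != where[b] for a, b in self.terminal_pairs)


@dataclass(frozen=True)
class GadgetParams:
    """The construction constants for an instance on H = (V_H, E_H)."""

    q: float        # |V_H|^5 + 1: weight of terminal H-edges
    q_prime: float  # q|E_H| + z: spine and non-edge weight
    z: float        # 2(C(|V_H|,2) - |E_H|): weight-1 edge budget

    @classmethod
    def for_instance(cls, instance: MulticutInstance) -> "GadgetParams":
        nv = len(instance.vertices)
        ne = len(instance.edges)
        z = 2.0 * (nv * (nv - 1) // 2 - ne)
        q = float(nv**5 + 1)
        return cls(q=q, q_prime=q * ne + z, z=z)


def primary(v: str) -> str:
    """Gadget name of the primary copy of an H-vertex."""
    return f"{v}.p"


def shadow(v: str) -> str:
    """Gadget name of the shadow copy of an H-vertex."""
    return f"{v}.s"


def build_multicut_gadget(
    instance: MulticutInstance,
) -> tuple[RelationGraph, WeightTable, GadgetParams]:
    """Translate a multicut instance into a weighted relation graph.

    Every gadget vertex gets its own species, so there are no forced
    paralogies.  |V_R| = 2|V_H|.
    """
    if len(instance.vertices) < 2:
        raise ValidationError("multicut gadget needs at least two H-vertices")
    params = GadgetParams.for_instance(instance)
    q, qp = params.q, params.q_prime

    genes = []
    species = {}
    for v in instance.vertices:
        for g in (primary(v), shadow(v)):
            genes.append(g)
            species[g] = f"sp_{g}"
    family = GeneFamily(genes, species)

    edges: dict[tuple[str, str], float] = {}
    for v in instance.vertices:  # spine edges
        edges[gene_pair(primary(v), shadow(v))] = qp
    for vi, vj in combinations(instance.vertices, 2):
        p = gene_pair(vi, vj)
        in_h = p in instance.edges
        if p in instance.terminal_pairs:
            edges[gene_pair(primary(vi), primary(vj))] = q if in_h else 1.0
        else:
            w = q / 2.0 if in_h else 1.0
            edges[gene_pair(primary(vi), shadow(vj))] = w
            edges[gene_pair(shadow(vi), primary(vj))] = w

    graph = RelationGraph(family, edges.keys())
    weight_map = dict(edges)
    for p in graph.non_edges():
        weight_map[p] = qp
    weights = WeightTable.complete(family, weight_map)
    return graph, weights, params


def multicut_to_editing(
    instance: MulticutInstance,
    gadget: RelationGraph,
    weights: WeightTable,
) -> EditSet:
    """Lift a multicut solution to a deletion-only editing of the gadget.

    The connected components of H minus the multicut partition V_H; the
    partition is lifted to the gadget (both copies of a vertex stay
    together) and every gadget edge crossing it is removed.  The result
    is P4-free and weighs at most q|E'_H| + z.
    """
    if instance.solution is None:
        raise ValidationError("the multicut instance carries no solution")
    if not instance.is_multicut(instance.solution):
        raise ValidationError("the attached edge set is not a multicut")
    comps = instance.components_after(instance.solution)
    where: dict[str, int] = {}
    for i, comp in enumerate(comps):
        for v in comp:
            where[primary(v)] = i
            where[shadow(v)] = i
    removed = frozenset(
        p for p in gadget.edges if where[p[0]] != where[p[1]]
    )
    return EditSet(frozenset(), removed, weights.total(removed))


def editing_to_multicut(
    edits: EditSet,
    instance: MulticutInstance,
    params: GadgetParams,
    bound: Optional[int] = None,
) -> frozenset[tuple[str, str]]:
    """Extract a multicut from a P4-free editing of the gadget.

    An H-pair joins the multicut when its direct weight-q edge, or its
    pair of weight-q/2 cross edges, was removed.  Valid whenever the
    editing weighs at most qW + z with W <= |E_H|; then the extracted set
    is a multicut of size at most W.  *bound* (W) defaults to the largest
    integer consistent with the editing weight.
    """
    if bound is None:
        # smallest integer W with total_weight <= qW + z
        bound = int(math.ceil((edits.total_weight - params.z) / params.q - 1e-9))
        bound = max(bound, 0)
    if edits.total_weight > params.q * bound + params.z + 1e-9:
        raise ValidationError(
            "editing weight exceeds the qW + z bound for the claimed W"
        )
    for v in instance.vertices:  # spine edges are never affordable to remove
        if gene_pair(primary(v), shadow(v)) in edits.removed:
            raise ValidationError("a spine edge was removed: weight bound violated")

    removed = edits.removed
    cut: set[tuple[str, str]] = set()
    for vi, vj in combinations(instance.vertices, 2):
        p = gene_pair(vi, vj)
        if p not in instance.edges:
            continue
        if p in instance.terminal_pairs:
            if gene_pair(primary(vi), primary(vj)) in removed:
                cut.add(p)
        else:
            if (
                gene_pair(primary(vi), shadow(vj)) in removed
                and gene_pair(shadow(vi), primary(vj)) in removed
            ):
                cut.add(p)
    return frozenset(cut)
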