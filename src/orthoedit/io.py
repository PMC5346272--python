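"""File formats: TSV tables for genes, relations, edits and multicut
instances; Newick for species trees and DS-trees.

All TSV files use '#' comment lines and tab separation.  Pairs are
written with the lexicographically smaller gene first.  Infinite weights
are written as the literal ``inf``.  Newick parsing goes through
dendropy; DS-trees carry their Dup/Spec labels as internal node labels
``D``/``S``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, TextIO

import dendropy

from .hardness import MulticutInstance
from .model import (
    DUP,
    SPEC,
    DSTree,
    EditSet,
    GeneFamily,
    Instance,
    RelationGraph,
    SpeciesTree,
    TreeNode,
    ValidationError,
    WeightTable,
    gene_pair,
    validate_instance,
)


class ParseError(ValidationError):
    """A file could not be parsed; carries the path and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")


def _rows(path) -> list[tuple[int, list[str]]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append((lineno, line.split("\t")))
    return out


# ---------------------------------------------------------------------------
# Genes and relations
# ---------------------------------------------------------------------------


def read_genes(path) -> GeneFamily:
    """Genes TSV: ``gene_id <TAB> species_id`` per row."""
    species = {}
    order = []
    for lineno, cols in _rows(path):
        if len(cols) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(cols)}")
        gene, sp = cols
        if gene in species:
            raise ParseError(path, lineno, f"duplicate gene {gene!r}")
        species[gene] = sp
        order.append(gene)
    if not order:
        raise ParseError(path, 0, "no genes")
    return GeneFamily(order, species)


def write_genes(family: GeneFamily, path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\tspecies_id\n")
        for g in family.genes:
            fh.write(f"{g}\t{family.species_of[g]}\n")


def _parse_weight(token: str, path, lineno: int) -> float:
    if token == "inf":
        return math.inf
    try:
        w = float(token)
    except ValueError:
        raise ParseError(path, lineno, f"bad weight {token!r}") from None
    if w < 0:
        raise ParseError(path, lineno, f"negative weight {token!r}")
    return w


def read_relations(
    family: GeneFamily, path
) -> tuple[RelationGraph, WeightTable]:
    """Relations TSV: ``gene_a <TAB> gene_b <TAB> orth|para <TAB> weight``.

    Unlisted pairs default to (para, 1.0).  Same-species pairs are forced
    to (para, inf); a file claiming them orthologous is an error.
    """
    known = set(family.genes)
    edges = set()
    weights = {}
    seen = set()
    for lineno, cols in _rows(path):
        if len(cols) not in (3, 4):
            raise ParseError(path, lineno, f"expected 3-4 columns, got {len(cols)}")
        a, b, rel = cols[:3]
        for g in (a, b):
            if g not in known:
                raise ParseError(path, lineno, f"unknown gene {g!r}")
        if a == b:
            raise ParseError(path, lineno, f"self-pair {a!r}")
        p = gene_pair(a, b)
        if p in seen:
            raise ParseError(path, lineno, f"duplicate pair {p}")
        seen.add(p)
        if rel not in ("orth", "para"):
            raise ParseError(path, lineno, f"relation must be orth/para, got {rel!r}")
        if family.same_species(*p):
            if rel == "orth":
                raise ParseError(
                    path, lineno,
                    f"forced paralogy violated: {p[0]} and {p[1]} share species "
                    f"{family.species_of[p[0]]!r}",
                )
            continue  # weight forced to inf regardless of file content
        if rel == "orth":
            edges.add(p)
        if len(cols) == 4:
            weights[p] = _parse_weight(cols[3], path, lineno)
    graph = RelationGraph(family, edges)
    return graph, WeightTable.complete(family, weights)


def write_relations(
    graph: RelationGraph, weights: Optional[WeightTable], path
) -> None:
    """Write every pair (edges and non-edges) with its weight, pairs in
    lexicographic order; round-trips through read_relations."""
    family = graph.family
    if weights is None:
        weights = WeightTable.complete(family)
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\trelation\tweight\n")
        from .model import all_pairs

        for p in all_pairs(family.genes):
            rel = "orth" if p in graph.edges else "para"
            w = weights[p]
            token = "inf" if math.isinf(w) else format(w, ".12g")
            fh.write(f"{p[0]}\t{p[1]}\t{rel}\t{token}\n")


def read_instance(
    genes_path, relations_path, species_tree_path=None
) -> Instance:
    """Parse and validate a full instance from files."""
    family = read_genes(genes_path)
    graph, weights = read_relations(family, relations_path)
    tree = read_species_tree(species_tree_path) if species_tree_path else None
    return validate_instance(family, graph, weights, tree)


# ---------------------------------------------------------------------------
# Edits
# ---------------------------------------------------------------------------


def write_edits(edits: EditSet, weights: WeightTable, path) -> None:
    """Edits TSV: ``op gene_a gene_b weight`` rows sorted by (op, pair),
    with the total weight in a trailing comment."""
    rows = []
    for p in sorted(edits.inserted):
        rows.append(("insert", p))
    for p in sorted(edits.removed):
        rows.append(("remove", p))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("# op\tgene_a\tgene_b\tweight\n")
        for op, p in rows:
            w = weights[p]
            token = "inf" if math.isinf(w) else format(w, ".12g")
            fh.write(f"{op}\t{p[0]}\t{p[1]}\t{token}\n")
        total = edits.total_weight
        token = "inf" if math.isinf(total) else format(total, ".12g")
        fh.write(f"# total_weight\t{token}\n")


def read_edits(path, weights: WeightTable) -> EditSet:
    inserted, removed = set(), set()
    for lineno, cols in _rows(path):
        if len(cols) != 4:
            raise ParseError(path, lineno, f"expected 4 columns, got {len(cols)}")
        op, a, b, _w = cols
        p = gene_pair(a, b)
        if op == "insert":
            inserted.add(p)
        elif op == "remove":
            removed.add(p)
        else:
            raise ParseError(path, lineno, f"op must be insert/remove, got {op!r}")
    return EditSet(inserted, removed, weights.total(inserted | removed))


# ---------------------------------------------------------------------------
# Trees (Newick)
# ---------------------------------------------------------------------------


def _from_dendropy(node) -> TreeNode:
    if node.is_leaf():
        label = node.taxon.label if node.taxon else node.label
        if label is None:
            raise ValidationError("Newick leaf without a label")
        return TreeNode(label=str(label).replace(" ", "_"))
    out = TreeNode()
    label = node.label
    if label in (DUP, SPEC):
        out.event = label
    for c in node.child_nodes():
        out.add_child(_from_dendropy(c))
    return out


def _parse_newick(text: str) -> TreeNode:
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return _from_dendropy(tree.seed_node)


def read_species_tree(path) -> SpeciesTree:
    """Rooted binary species tree from a Newick file."""
    text = Path(path).read_text()
    return SpeciesTree(_parse_newick(text))


def read_dstree(path, family: Optional[GeneFamily] = None) -> DSTree:
    """DS-tree from Newick with internal labels D (Dup) / S (Spec)."""
    text = Path(path).read_text()
    root = _parse_newick(text)
    for v in root.postorder():
        if not v.is_leaf and v.event not in (DUP, SPEC):
            raise ValidationError(
                "DS-tree Newick internal nodes must be labelled D or S"
            )
    return DSTree(root=root, family=family)


def _newick(node: TreeNode, with_events: bool) -> str:
    if node.is_leaf:
        return node.label
    inner = ",".join(_newick(c, with_events) for c in node.children)
    label = node.event if (with_events and node.event) else ""
    return f"({inner}){label}"


def write_species_tree(tree: SpeciesTree, path) -> None:
    Path(path).write_text(_newick(tree.root, with_events=False) + ";\n")


def write_dstree(tree: DSTree, path) -> None:
    """DS-tree as Newick with internal labels S/D; parses back equal."""
    genes = tree.root.leaf_labels()
    if len(set(genes)) != len(genes):
        raise ValidationError("duplicate gene labels in DS-tree")
    Path(path).write_text(_newick(tree.root, with_events=True) + ";\n")


def dstree_newick(tree: DSTree) -> str:
    return _newick(tree.root, with_events=True) + ";"


# ---------------------------------------------------------------------------
# Multicut instances
# ---------------------------------------------------------------------------


def read_multicut(path) -> MulticutInstance:
    """Multicut TSV: rows ``vertex v``, ``edge u v`` and ``terminal u v``."""
    vertices, edges, terminals = [], [], []
    for lineno, cols in _rows(path):
        kind = cols[0]
        if kind == "vertex" and len(cols) == 2:
            vertices.append(cols[1])
        elif kind == "edge" and len(cols) == 3:
            edges.append((cols[1], cols[2]))
            vertices.extend(cols[1:3])
        elif kind == "terminal" and len(cols) == 3:
            terminals.append((cols[1], cols[2]))
            vertices.extend(cols[1:3])
        else:
            raise ParseError(path, lineno, f"bad row {cols!r}")
    return MulticutInstance(vertices, edges, terminals)


def write_multicut(instance: MulticutInstance, path) -> None:
    with open(path, "w") as fh:
        fh.write("# kind\tu\tv\n")
        for v in instance.vertices:
            fh.write(f"vertex\t{v}\n")
        for a, b in sorted(instance.edges):
            fh.write(f"edge\t{a}\t{b}\n")
        for a, b in sorted(instance.terminal_pairs):
            fh.write(f"terminal\t{a}\t{b}\n")
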