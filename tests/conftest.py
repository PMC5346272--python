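"""Shared fixtures and builders for the test suite.

All fixtures are generated programmatically; the convention throughout
is gene names like ``a1, a2, b1`` whose leading letter is the species
(as in ``s(a1) = a``), which keeps tiny examples readable.
"""

from __future__ import annotations

import pytest

from orthoedit.model import GeneFamily, RelationGraph, SpeciesTree, TreeNode, WeightTable
from orthoedit import io as oio


def family_from_names(*genes: str) -> GeneFamily:
    """Gene family where each gene's species is its leading alpha prefix
    (a1 -> a, b2 -> b)."""
    species = {g: g.rstrip("0123456789") for g in genes}
    return GeneFamily(genes, species)


def distinct_family(n: int) -> GeneFamily:
    """n genes x0..x{n-1}, each in its own species."""
    genes = [f"x{i}" for i in range(n)]
    return GeneFamily(genes, {g: f"sp_{g}" for g in genes})


def graph(edges, *genes) -> RelationGraph:
    """Relation graph over family_from_names(*genes) with the given edges
    (either 'a1-b1' strings or pair tuples)."""
    fam = family_from_names(*genes)
    pairs = []
    for e in edges:
        if isinstance(e, str):
            a, b = e.split("-")
            pairs.append((a, b))
        else:
            pairs.append(tuple(e))
    return RelationGraph(fam, pairs)


def newick_species_tree(text: str) -> SpeciesTree:
    import dendropy

    from orthoedit.io import _from_dendropy

    tree = dendropy.Tree.get(
        data=text if text.endswith(";") else text + ";",
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return SpeciesTree(_from_dendropy(tree.seed_node))


@pytest.fixture
def abc_tree() -> SpeciesTree:
    """Species tree ((a,b),c)."""
    return newick_species_tree("((a,b),c)")


@pytest.fixture
def abcd_tree() -> SpeciesTree:
    """Species tree ((a,b),(c,d))."""
    return newick_species_tree("((a,b),(c,d))")
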