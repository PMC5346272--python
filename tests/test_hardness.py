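import math
from itertools import combinations

import pytest

from orthoedit import oracle, synth
from orthoedit.cograph import is_p4_free
from orthoedit.hardness import (
    GadgetParams,
    MulticutInstance,
    build_multicut_gadget,
    editing_to_multicut,
    multicut_to_editing,
    primary,
    shadow,
)
from orthoedit.model import ValidationError, gene_pair


def path_instance(solution=None):
    """H = path u - v - w with terminal pair {u, w}."""
    return MulticutInstance(
        ["u", "v", "w"], [("u", "v"), ("v", "w")], [("u", "w")], solution=solution
    )


class TestGadgetConstruction:
    def test_params_three_vertices(self):
        params = GadgetParams.for_instance(path_instance())
        assert params.q == 3**5 + 1 == 244
        assert params.z == 2 * (3 - 2) == 2
        assert params.q_prime == 244 * 2 + 2

    def test_vertex_doubling_and_fresh_species(self):
        graph, weights, _ = build_multicut_gadget(path_instance())
        assert graph.n == 6
        species = {graph.family.species_of[g] for g in graph.family.genes}
        assert len(species) == 6  # no forced paralogs

    def test_edge_weights_follow_construction(self):
        inst = path_instance()
        graph, weights, params = build_multicut_gadget(inst)
        # spine edges
        for v in inst.vertices:
            assert weights[gene_pair(primary(v), shadow(v))] == params.q_prime
        # terminal pair {u,w} not an H-edge -> direct edge of weight 1
        assert weights[gene_pair(primary("u"), primary("w"))] == 1.0
        # non-terminal H-edge {u,v} -> two cross edges of weight q/2
        assert weights[gene_pair(primary("u"), shadow("v"))] == params.q / 2
        assert weights[gene_pair(shadow("u"), primary("v"))] == params.q / 2
        # non-edges carry q'
        assert weights[gene_pair(primary("u"), primary("v"))] == params.q_prime
        assert gene_pair(primary("u"), primary("v")) not in graph.edges

    @pytest.mark.parametrize("seed", range(20))
    def test_weight1_edge_count_bounded(self, seed):
        inst = synth.random_multicut_instance(4, 0.5, 2, seed)
        graph, weights, params = build_multicut_gadget(inst)
        ones = sum(1 for p in graph.edges if weights[p] == 1.0)
        assert ones <= params.z

    def test_terminal_h_edge_induces_p4(self):
        # for a terminal pair that is also an H-edge, the quadruple
        # shadow-primary-primary-shadow is an induced P4
        inst = MulticutInstance(["u", "v"], [("u", "v")], [("u", "v")])
        graph, _, _ = build_multicut_gadget(inst)
        quad = [shadow("u"), primary("u"), primary("v"), shadow("v")]
        adj = graph.adjacency()
        edges_in_quad = {
            (a, b)
            for a, b in combinations(sorted(quad), 2)
            if b in adj[a]
        }
        expected = {
            gene_pair(shadow("u"), primary("u")),
            gene_pair(primary("u"), primary("v")),
            gene_pair(primary("v"), shadow("v")),
        }
        assert edges_in_quad == expected


class TestTranslations:
    def test_lift_single_edge_multicut(self):
        inst = MulticutInstance(["u", "v"], [("u", "v")], [("u", "v")],
                                solution=[("u", "v")])
        graph, weights, params = build_multicut_gadget(inst)
        edits = multicut_to_editing(inst, graph, weights)
        assert gene_pair(primary("u"), primary("v")) in edits.removed
        assert edits.total_weight <= params.q * 1 + params.z
        assert is_p4_free(edits.apply(graph))

    def test_remove_all_h_edges(self):
        inst = MulticutInstance(
            ["u", "v", "w"], [("u", "v"), ("v", "w")], [("u", "w")],
            solution=[("u", "v"), ("v", "w")],
        )
        graph, weights, params = build_multicut_gadget(inst)
        edits = multicut_to_editing(inst, graph, weights)
        assert is_p4_free(edits.apply(graph))
        assert edits.total_weight <= params.q * 2 + params.z

    def test_empty_terminals_empty_solution(self):
        # with no terminals the empty set is a multicut; the lifted edit
        # stays within the z budget (only weight-1 edges may cross)
        inst = MulticutInstance(["u", "v"], [], [], solution=[])
        graph, weights, params = build_multicut_gadget(inst)
        edits = multicut_to_editing(inst, graph, weights)
        assert edits.total_weight <= params.z
        assert is_p4_free(edits.apply(graph))

    def test_invalid_multicut_rejected(self):
        inst = path_instance(solution=[])
        graph, weights, _ = build_multicut_gadget(inst)
        with pytest.raises(ValidationError, match="not a multicut"):
            multicut_to_editing(inst, graph, weights)

    def test_round_trip_never_grows(self):
        inst = path_instance(solution=[("u", "v")])
        graph, weights, params = build_multicut_gadget(inst)
        edits = multicut_to_editing(inst, graph, weights)
        back = editing_to_multicut(edits, inst, params)
        assert inst.is_multicut(back)
        assert len(back) <= len(inst.solution)

    def test_extraction_from_oracle_optimum(self):
        # optimal deletion-only editing of the 6-vertex gadget for the
        # path instance extracts a size-1 multicut
        inst = path_instance()
        graph, weights, params = build_multicut_gadget(inst)
        opt = oracle.brute_force_edit(graph, weights, deletion_only=True,
                                      max_vertices=6)
        back = editing_to_multicut(opt.argmin, inst, params)
        assert inst.is_multicut(back) and len(back) == 1
        # no spine edge is ever removed within the bound
        for v in inst.vertices:
            assert gene_pair(primary(v), shadow(v)) not in opt.argmin.removed

    def test_exhaustive_tiny_instances(self):
        # all multicut instances on 3 vertices: every valid solution lifts
        # to a P4-free editing within the bound and extracts back <= W
        verts = ["u", "v", "w"]
        pairs = list(combinations(verts, 2))
        for edge_bits in range(2 ** len(pairs)):
            edges = [p for i, p in enumerate(pairs) if (edge_bits >> i) & 1]
            for x_bits in range(2 ** len(pairs)):
                terminals = [p for i, p in enumerate(pairs) if (x_bits >> i) & 1]
                base = MulticutInstance(verts, edges, terminals)
                graph, weights, params = build_multicut_gadget(base)
                for sol_bits in range(2 ** len(edges)):
                    sol = [p for i, p in enumerate(edges) if (sol_bits >> i) & 1]
                    inst = MulticutInstance(verts, edges, terminals, solution=sol)
                    if not inst.is_multicut(inst.solution):
                        continue
                    edits = multicut_to_editing(inst, graph, weights)
                    w_bound = params.q * len(sol) + params.z
                    assert edits.total_weight <= w_bound + 1e-9
                    assert is_p4_free(edits.apply(graph))
                    back = editing_to_multicut(edits, base, params, bound=len(sol))
                    assert base.is_multicut(back)
                    assert len(back) <= len(sol)
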