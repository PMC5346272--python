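import math
import random

import pytest

from orthoedit import oracle, synth
from orthoedit.cograph import agreement, is_p4_free, relations_from_dstree
from orthoedit.consistency import is_s_consistent_graph, is_s_consistent_tree
from orthoedit.editing import (
    baseline_agreement,
    min_cut_weighted,
    mincut_cograph_editing,
    mincut_cograph_editing_cons,
    species_cut,
)
from orthoedit.model import RelationGraph, SPEC, ValidationError, WeightTable

from conftest import distinct_family, family_from_names, graph, newick_species_tree


class TestMinCut:
    def test_two_vertices_single_edge(self):
        cut = min_cut_weighted(["a", "b"], {("a", "b"): 5.0})
        assert cut.weight == 5.0 and cut.crossing == frozenset({("a", "b")})

    def test_disconnected_graph_free_cut(self):
        cut = min_cut_weighted(["a", "b", "c", "d"], {("a", "b"): 2.0, ("c", "d"): 3.0})
        assert cut.weight == 0.0
        assert {cut.x, cut.y} == {frozenset("ab"), frozenset("cd")}

    def test_double_star_cut_weight_one(self):
        g, w = synth.double_star(8)
        cut = min_cut_weighted(g.vertices, {p: w[p] for p in g.edges})
        assert cut.weight == 1.0

    def test_infinite_pairs_never_separated_when_avoidable(self):
        cut = min_cut_weighted(
            ["a", "b", "c"],
            {("a", "b"): math.inf, ("a", "c"): 2.0, ("b", "c"): 3.0},
        )
        assert cut.weight == 5.0  # isolate c, keeping the infinite pair whole

    def test_forced_infinite_cut_reported_infinite(self):
        cut = min_cut_weighted(["a", "b"], {("a", "b"): math.inf})
        assert math.isinf(cut.weight)

    def test_fewer_than_two_vertices_rejected(self):
        with pytest.raises(ValidationError):
            min_cut_weighted(["a"], {})

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 10)
        verts = [f"x{i:02d}" for i in range(n)]
        from itertools import combinations

        pw = {
            p: rng.choice([0.0, 1.0, rng.uniform(0.1, 3.0)])
            for p in combinations(verts, 2)
            if rng.random() < 0.6
        }
        fast = min_cut_weighted(verts, pw)
        slow = oracle.brute_force_min_cut(verts, pw)
        assert fast.weight == pytest.approx(slow.weight)


class TestSpeciesCut:
    def test_single_species_absent(self, abcd_tree):
        fam = family_from_names("a1", "a2")
        assert species_cut(["a1", "a2"], fam, abcd_tree) is None

    def test_root_split_of_restricted_tree(self, abcd_tree):
        fam = family_from_names("a1", "b1", "c1")
        x, y = species_cut(["a1", "b1", "c1"], fam, abcd_tree)
        assert {x, y} == {frozenset({"a1", "b1"}), frozenset({"c1"})}

    def test_crossing_pairs_never_same_species(self, abcd_tree):
        fam = family_from_names("a1", "a2", "b1", "c1", "c2")
        x, y = species_cut(fam.genes, fam, abcd_tree)
        for g1 in x:
            for g2 in y:
                assert fam.species_of[g1] != fam.species_of[g2]


class TestGreedyEditing:
    def test_cograph_costs_nothing(self):
        fam = distinct_family(7)
        g = synth.random_cograph(fam, seed=5)
        res = mincut_cograph_editing(g, synth.unit_weights(fam))
        assert res.cost == 0.0 and res.edits.size == 0
        assert res.edited_graph == g

    def test_p4_path_fixed_at_optimum(self):
        g = graph(["a1-b1", "b1-c1", "c1-d1"], "a1", "b1", "c1", "d1")
        w = WeightTable.complete(g.family)
        res = mincut_cograph_editing(g, w)
        assert res.cost == 1.0
        assert oracle.brute_force_edit(g, w).optimum_weight == 1.0
        assert is_p4_free(res.edited_graph)

    def test_double_star_regression(self):
        # tightness family: optimum 1, greedy may pay up to n - 3 = 5;
        # under the pinned deterministic tie-breaks it pays 3
        g, w = synth.double_star(8)
        res = mincut_cograph_editing(g, w)
        assert 1.0 <= res.cost <= 5.0
        assert res.cost == 3.0
        assert is_p4_free(res.edited_graph)

    def test_result_invariants(self):
        for seed in range(25):
            rng = random.Random(seed)
            n = rng.randint(2, 8)
            fam, _ = synth.random_species_instance(rng.randint(1, 4), n, seed)
            g = synth.random_graph(fam, 0.5, seed + 99)
            w = synth.random_weights(fam, seed + 5)
            res = mincut_cograph_editing(g, w)
            assert is_p4_free(res.edited_graph)
            assert relations_from_dstree(res.tree) == res.edited_graph
            assert res.edits.apply(g) == res.edited_graph
            assert not (res.edits.inserted & res.edits.removed)
            assert res.cost == pytest.approx(w.total(res.edits.inserted | res.edits.removed))
            # no same-species pair is ever inserted
            assert all(not fam.same_species(*p) for p in res.edits.inserted)

    def test_deletion_only_never_inserts(self):
        for seed in range(15):
            rng = random.Random(seed)
            fam, _ = synth.random_species_instance(2, rng.randint(3, 8), seed)
            g = synth.random_graph(fam, 0.6, seed + 7)
            res = mincut_cograph_editing(g, synth.unit_weights(fam), deletion_only=True)
            assert res.edits.inserted == frozenset()
            assert is_p4_free(res.edited_graph)
            assert relations_from_dstree(res.tree) == res.edited_graph

    @pytest.mark.parametrize("seed", range(30))
    def test_within_n_times_optimum(self, seed):
        rng = random.Random(seed)
        n = rng.randint(4, 7)
        fam, _ = synth.random_species_instance(rng.randint(2, n), n, seed)
        g = synth.random_graph(fam, 0.5, seed + 31)
        w = synth.unit_weights(fam) if seed % 2 else synth.random_weights(fam, seed)
        res = mincut_cograph_editing(g, w)
        opt = oracle.brute_force_edit(g, w)
        assert res.cost <= n * opt.optimum_weight + 1e-9


class TestGreedyConsistent:
    def test_consistent_input_costs_nothing(self, abc_tree):
        # one gene per species, relations of the all-Spec tree shaped like S
        g = graph(["a1-b1", "a1-c1", "b1-c1"], "a1", "b1", "c1")
        res = mincut_cograph_editing_cons(g, WeightTable.complete(g.family), abc_tree)
        assert res.cost == 0.0
        assert is_s_consistent_tree(res.tree, abc_tree)[0]

    def test_satisfiable_but_inconsistent_path(self, abc_tree):
        # MinWES optimum is 0 but the consistent optimum is 1; the greedy
        # matches the consistent optimum here
        g = graph(["a1-b1", "a1-c1"], "a1", "b1", "c1")
        w = WeightTable.complete(g.family)
        res = mincut_cograph_editing_cons(g, w, abc_tree)
        opt = oracle.brute_force_edit_cons(g, w, abc_tree)
        assert opt.optimum_weight == 1.0
        assert res.cost == opt.optimum_weight

    def test_every_spec_node_follows_species_tree(self, abcd_tree):
        fam = family_from_names("a1", "a2", "b1", "c1", "d1")
        g = synth.random_graph(fam, 0.5, seed=3)
        res = mincut_cograph_editing_cons(g, synth.unit_weights(fam), abcd_tree)
        ok, violating = is_s_consistent_tree(res.tree, abcd_tree)
        assert ok and violating is None
        assert is_s_consistent_graph(res.edited_graph, abcd_tree)

    @pytest.mark.parametrize("seed", range(20))
    def test_within_n_times_consistent_optimum(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 6)
        fam, st = synth.random_species_instance(rng.randint(2, min(4, n)), n, seed)
        g = synth.random_graph(fam, 0.5, seed + 61)
        w = synth.unit_weights(fam) if seed % 2 else synth.random_weights(fam, seed)
        res = mincut_cograph_editing_cons(g, w, st)
        opt = oracle.brute_force_edit_cons(g, w, st)
        assert res.cost <= n * opt.optimum_weight + 1e-9
        assert is_s_consistent_tree(res.tree, st)[0]

    def test_requires_species_tree(self):
        g = graph([], "a1", "b1")
        with pytest.raises(ValidationError):
            mincut_cograph_editing_cons(g, WeightTable.complete(g.family), None)


class TestBaseline:
    def test_edgeless_input_perfect_agreement(self):
        g = graph([], "a1", "a2", "b1", "c1")
        chosen, tree, val = baseline_agreement(g)
        assert chosen.edges == frozenset() and val == 6

    def test_complete_multipartite_input_perfect_agreement(self, abc_tree):
        g = graph(["a1-b1", "a1-c1", "b1-c1", "a2-b1", "a2-c1"], "a1", "a2", "b1", "c1")
        chosen, tree, val = baseline_agreement(g, abc_tree)
        assert chosen == g and val == 6
        assert is_s_consistent_tree(tree, abc_tree)[0]

    @pytest.mark.parametrize("seed", range(30))
    def test_half_agreement_bound(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 9)
        fam, st = synth.random_species_instance(rng.randint(1, 4), n, seed)
        g = synth.random_graph(fam, rng.random(), seed + 17)
        chosen, tree, val = baseline_agreement(g, st)
        total = n * (n - 1) // 2
        assert val >= (total + 1) // 2
        assert agreement(g, relations_from_dstree(tree)) == val
        assert is_p4_free(chosen)

    def test_lemma6_identity(self):
        # A(R, R') + A(R, R'') >= C(n,2), equality when all species differ
        fam = family_from_names("a1", "b1", "c1", "d1")
        g = synth.random_graph(fam, 0.5, seed=8)
        edgeless = RelationGraph(fam, [])
        from orthoedit.model import all_pairs

        multipartite = RelationGraph(
            fam, [p for p in all_pairs(fam.genes) if not fam.same_species(*p)]
        )
        assert agreement(g, edgeless) + agreement(g, multipartite) == 6

        fam2 = family_from_names("a1", "a2", "b1", "c1")
        g2 = synth.random_graph(fam2, 0.5, seed=9)
        e2 = RelationGraph(fam2, [])
        m2 = RelationGraph(
            fam2, [p for p in all_pairs(fam2.genes) if not fam2.same_species(*p)]
        )
        assert agreement(g2, e2) + agreement(g2, m2) >= 6
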