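"""Exact and heuristic tree search, collapsing and consensus."""

import pytest

import parsclad as pc
from parsclad.errors import CapExceededError


def canon_set(trees):
    return {pc.canonical_id(t) for t in trees}


class TestExhaustive:
    def test_four_taxon_split_recovered(self):
        m = pc.parse_matrix("A,1\nB,1\nC,0\nD,0\n", "csv")
        res = pc.exhaustive_search(m)
        assert res.best_length == 1
        assert len(res.best_trees_binary) == 1
        assert frozenset({"A", "B"}) in res.best_trees_binary[0].splits() or \
            frozenset({"C", "D"}) in res.best_trees_binary[0].splits()
        assert res.n_topologies_examined == 3

    def test_perfect_hierarchy_unique_optimum(self):
        truth = pc.caterpillar_tree([f"x{i}" for i in range(6)])
        m = pc.simulate_perfect_hierarchy(truth, 1)
        res = pc.exhaustive_search(m)
        assert res.best_length == m.n_characters == 3
        assert canon_set(res.best_trees_binary) == {pc.canonical_id(truth)}

    def test_cap_refusal(self):
        truth = pc.random_topology([f"t{i}" for i in range(12)], seed=1)
        m = pc.simulate_perfect_hierarchy(truth, 1)
        with pytest.raises(CapExceededError):
            pc.exhaustive_search(m)


class TestBranchAndBound:
    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_exhaustive(self, seed):
        n = 6 + seed % 3
        tree = pc.random_topology([f"t{i}" for i in range(n)], seed=seed,
                                  branch_mean=0.4)
        m, _ = pc.simulate_mk(pc.SimulationSpec(tree=tree, n_characters=15,
                                                seed=seed))
        ex = pc.exhaustive_search(m)
        bb = pc.branch_and_bound(m)
        assert bb.best_length == ex.best_length
        assert canon_set(bb.best_trees_binary) == canon_set(ex.best_trees_binary)

    def test_bundled_matrix_optimum(self, saltans_bnb):
        assert saltans_bnb.best_length == 24
        assert saltans_bnb.n_topologies_examined < 34_459_425
        assert len(saltans_bnb.best_trees_binary) == 3
        assert len(saltans_bnb.best_trees_collapsed) == 1

    def test_three_optima_differ_only_in_saltans_trio(self, saltans_bnb):
        trio = frozenset({"prosaltans", "lusaltans", "austrosaltans"})
        labels = frozenset(saltans_bnb.best_trees_binary[0].leaf_labels())
        split_sets = [t.splits() for t in saltans_bnb.best_trees_binary]
        shared = set.intersection(*split_sets)
        for splits in split_sets:
            extra = splits - shared
            assert len(extra) == 1
            side = next(iter(extra))
            small = side if len(side) <= len(labels - side) else labels - side
            assert small < trio  # a pair within the unresolved trio

    def test_four_taxa_identical_to_exhaustive(self):
        m = pc.parse_matrix("A,1,0\nB,1,1\nC,0,1\nD,0,0\n", "csv")
        assert pc.branch_and_bound(m).best_length == pc.exhaustive_search(m).best_length

    def test_greedy_bound_dominates_final_length(self, saltans_bnb):
        (bound_event,) = [e for e in saltans_bnb.search_log
                          if e["event"] == "initial_bound"]
        assert bound_event["length"] >= saltans_bnb.best_length

    def test_low_supplied_bound_triggers_clean_restart(self, saltans_matrix):
        res = pc.branch_and_bound(saltans_matrix, initial_bound=10)
        assert res.best_length == 24
        assert len(res.best_trees_binary) == 3


class TestRatchet:
    def test_requires_seed(self, saltans_matrix):
        with pytest.raises(Exception, match="seed"):
            pc.ratchet_search(saltans_matrix, iterations=1)

    def test_deterministic_given_seed(self, saltans_matrix):
        a = pc.ratchet_search(saltans_matrix, iterations=5, seed=11)
        b = pc.ratchet_search(saltans_matrix, iterations=5, seed=11)
        assert a.best_length == b.best_length
        assert canon_set(a.best_trees_binary) == canon_set(b.best_trees_binary)
        assert a.search_log == b.search_log

    def test_compatible_data_found_in_one_iteration(self):
        truth = pc.caterpillar_tree([f"x{i}" for i in range(7)])
        m = pc.simulate_perfect_hierarchy(truth, 1)
        res = pc.ratchet_search(m, iterations=1, seed=3)
        assert res.best_length == m.n_characters
        assert pc.canonical_id(truth) in canon_set(res.best_trees_binary)

    def test_finds_exact_optimum_across_seeds(self, saltans_matrix):
        hits = sum(
            pc.ratchet_search(saltans_matrix, iterations=50, seed=s).best_length == 24
            for s in range(1, 21))
        assert hits >= 19


class TestCollapse:
    def test_bundled_optima_collapse_to_single_tree(self, saltans_bnb, saltans_matrix):
        from tests.conftest import has_bipartition
        collapsed = pc.collapse_and_dedup(saltans_bnb.best_trees_binary, saltans_matrix)
        assert len(collapsed) == 1
        trio = {"prosaltans", "lusaltans", "austrosaltans"}
        # the trio clade itself is supported; its internal resolution is not
        assert has_bipartition(collapsed[0], trio)
        assert not any(has_bipartition(collapsed[0], pair)
                       for pair in [{"prosaltans", "lusaltans"},
                                    {"prosaltans", "austrosaltans"},
                                    {"lusaltans", "austrosaltans"}])
        assert has_bipartition(collapsed[0], trio | {"saltans"})

    def test_collapse_preserves_length(self, saltans_bnb, saltans_matrix):
        for t in saltans_bnb.best_trees_collapsed:
            assert pc.tree_length(t, saltans_matrix).total_steps == 24

    def test_supported_tree_unchanged(self):
        truth = pc.caterpillar_tree([f"x{i}" for i in range(6)])
        m = pc.simulate_perfect_hierarchy(truth, 1)
        res = pc.exhaustive_search(m)
        (only,) = pc.collapse_and_dedup(res.best_trees_binary, m)
        assert pc.canonical_id(only) == pc.canonical_id(truth)
        assert len(only.splits()) == 3

    def test_idempotent(self, saltans_bnb, saltans_matrix):
        once = pc.collapse_and_dedup(saltans_bnb.best_trees_binary, saltans_matrix)
        twice = pc.collapse_and_dedup(once, saltans_matrix)
        assert canon_set(once) == canon_set(twice)

    def test_duplicates_dedup(self, saltans_bnb, saltans_matrix):
        tree = saltans_bnb.best_trees_binary[0]
        out = pc.collapse_and_dedup([tree, tree.copy()], saltans_matrix, rule="none")
        assert len(out) == 1


class TestStrictConsensus:
    def test_identical_trees(self):
        t = pc.parse_newick("(A,B,(C,(D,E)));")
        cons = pc.strict_consensus([t, t.copy()])
        assert pc.canonical_id(cons) == pc.canonical_id(t)

    def test_conflicting_quartets_give_star(self):
        a = pc.parse_newick("(A,B,(C,D));")
        b = pc.parse_newick("(A,C,(B,D));")
        cons = pc.strict_consensus([a, b])
        assert cons.splits() == set()

    def test_consensus_splits_contained_in_all_inputs(self, saltans_bnb):
        cons = pc.strict_consensus(saltans_bnb.best_trees_binary)
        for t in saltans_bnb.best_trees_binary:
            assert cons.splits() <= t.splits()

    def test_bundled_consensus_shows_trio_polytomy(self, saltans_bnb):
        cons = pc.strict_consensus(saltans_bnb.best_trees_binary)
        # 11-taxon binary tree has 8 non-trivial splits; one is lost
        assert len(cons.splits()) == 7

    def test_leafset_mismatch_rejected(self):
        with pytest.raises(Exception, match="leaf"):
            pc.strict_consensus([pc.parse_newick("(A,B,(C,D));"),
                                 pc.parse_newick("(A,B,(C,E));")])
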