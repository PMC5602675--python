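import numpy as np
import pytest

from conftest import random_binary_matrix
from mosaweak.matrix_io import CharacterMatrix, CharacterSettings, parse_tnt
from mosaweak.parsimony import TreeScorer
from mosaweak.search import (Constraint, SearchConfig, constrained_search,
                             enumerate_unrooted_trees, exhaustive_search,
                             has_clade, random_addition_tree, search_battery,
                             spr_neighbors, swap_to_optimum, tbr_neighbors)
from mosaweak.tree import Tree, TreeError


def _keys(trees):
    return {frozenset(t.bipartitions()) for t in trees}


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(3, 1), (4, 3), (5, 15), (6, 105)])
    def test_counts(self, n, count):
        taxa = [chr(65 + i) for i in range(n)]
        trees = list(enumerate_unrooted_trees(taxa))
        assert len(trees) == count
        assert len(_keys(trees)) == count


class TestRandomAddition:
    def test_three_taxa_unique_topology(self):
        m = parse_tnt("xread 1 3 A 0 B 0 C 1 ;")
        t1 = random_addition_tree(m, seed=1)
        t2 = random_addition_tree(m, seed=99)
        assert t1.canonical_key() == t2.canonical_key()

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(0)
        m = random_binary_matrix(rng, 8, 15)
        a = random_addition_tree(m, seed=5)
        b = random_addition_tree(m, seed=5)
        assert a.canonical_key() == b.canonical_key()

    def test_clean_signal_reaches_minimum(self):
        # perfectly compatible characters: addition tree is homoplasy-free
        m = parse_tnt(
            "xread 4 6 A 0000 B 1000 C 1100 D 1110 E 1111 F 0000 ;")
        scorer = TreeScorer(m)
        t = random_addition_tree(m, seed=3)
        assert scorer.length(t) == scorer.sum_min


class TestSwapToOptimum:
    def test_stays_at_isolated_optimum(self):
        m = parse_tnt("xread 3 4 A 000 B 001 C 110 D 111 ;")
        start = exhaustive_search(m).trees[0]
        result = swap_to_optimum(start, m)
        assert _keys(result.trees) == _keys([start])

    @pytest.mark.parametrize("swap", ["SPR", "TBR"])
    def test_island_equals_exhaustive_on_six_taxa(self, swap):
        rng = np.random.default_rng(8)
        for trial in range(4):
            m = random_binary_matrix(rng, 6, 9)
            ex = exhaustive_search(m)
            got = search_battery(m, None, SearchConfig(
                n_replicates=6, seed=trial, swap=swap, collapse_rule="NONE"))
            assert got.best_score == ex.best_score
            assert _keys(got.trees) == _keys(ex.trees)


class TestSearchBattery:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        m = random_binary_matrix(rng, 7, 12)
        cfg = SearchConfig(n_replicates=5, seed=11)
        r1 = search_battery(m, None, cfg)
        r2 = search_battery(m, None, cfg)
        assert [t.to_newick(with_lengths=False) for t in r1.trees] == \
            [t.to_newick(with_lengths=False) for t in r2.trees]

    def test_more_replicates_never_worse(self):
        rng = np.random.default_rng(14)
        m = random_binary_matrix(rng, 7, 10)
        few = search_battery(m, None, SearchConfig(n_replicates=1, seed=0))
        many = search_battery(m, None, SearchConfig(n_replicates=8, seed=0))
        assert many.best_score <= few.best_score

    def test_returned_trees_rescore_to_best(self):
        rng = np.random.default_rng(21)
        m = random_binary_matrix(rng, 7, 10)
        res = search_battery(m, None, SearchConfig(n_replicates=4, seed=1,
                                                   collapse_rule="NONE"))
        scorer = TreeScorer(m)
        for t in res.trees:
            assert scorer.length(t) == res.best_score

    def test_iw_battery_matches_exhaustive(self):
        rng = np.random.default_rng(29)
        m = random_binary_matrix(rng, 6, 8)
        for K in (3.0, 6.0, 9.0):
            s = CharacterSettings(weighting="IMPLIED", K=K)
            ex = exhaustive_search(m, s)
            got = search_battery(m, s, SearchConfig(n_replicates=5, seed=2,
                                                    collapse_rule="NONE"))
            assert got.best_score == pytest.approx(ex.best_score, abs=1e-8)


class TestConstraints:
    def test_forbid_absent_clade_is_free(self):
        rng = np.random.default_rng(33)
        m = random_binary_matrix(rng, 6, 10)
        ex = exhaustive_search(m)
        # find a clade absent from every optimum
        taxa = list(m.taxa)
        absent = None
        for a in taxa:
            for b in taxa:
                if a < b and all(not has_clade(t, frozenset({a, b}))
                                 for t in ex.trees):
                    absent = frozenset({a, b})
                    break
            if absent:
                break
        assert absent is not None
        cfg = SearchConfig(n_replicates=5, seed=0,
                           constraint=Constraint(clade=absent, mode="FORBID"))
        got = constrained_search(m, None, cfg)
        assert got.best_score == ex.best_score

    def test_forbidden_optimum_matches_enumeration(self):
        rng = np.random.default_rng(39)
        for trial in range(3):
            m = random_binary_matrix(rng, 6, 10)
            clade = frozenset(list(m.taxa)[1:3])
            brute = exhaustive_search(
                m, constraint=Constraint(clade=clade, mode="FORBID"))
            cfg = SearchConfig(n_replicates=6, seed=trial,
                               constraint=Constraint(clade=clade, mode="FORBID"),
                               collapse_rule="NONE")
            got = constrained_search(m, None, cfg)
            assert got.best_score == brute.best_score
            assert _keys(got.trees) == _keys(brute.trees)

    def test_constrained_never_better(self):
        rng = np.random.default_rng(41)
        m = random_binary_matrix(rng, 6, 10)
        ex = exhaustive_search(m)
        clade = frozenset(list(m.taxa)[2:4])
        cfg = SearchConfig(n_replicates=5, seed=0,
                           constraint=Constraint(clade=clade, mode="FORBID"))
        got = constrained_search(m, None, cfg)
        assert got.best_score >= ex.best_score

    def test_unknown_taxa_rejected(self):
        rng = np.random.default_rng(43)
        m = random_binary_matrix(rng, 5, 5)
        cfg = SearchConfig(constraint=Constraint(clade=frozenset({"ZZ", "A"})))
        with pytest.raises(TreeError):
            constrained_search(m, None, cfg)


class TestTruncation:
    def test_max_saved_trees_flags_truncation(self):
        # an all-ambiguous matrix makes every topology optimal
        m = parse_tnt("xread 2 6 A ?? B ?? C ?? D ?? E ?? F ?? ;")
        res = search_battery(m, None, SearchConfig(n_replicates=1, seed=0,
                                                   max_saved_trees=3,
                                                   collapse_rule="NONE"))
        assert res.truncated
        assert len(res.trees) <= 3


class TestNeighborhoods:
    def test_spr_neighbors_share_leafset(self):
        t = Tree.from_newick("((A,B),((C,D),(E,F)));")
        for nb in spr_neighbors(t):
            assert nb.leaf_labels() == t.leaf_labels()

    def test_tbr_superset_of_spr(self):
        t = Tree.from_newick("((A,B),((C,D),(E,F)));")
        spr = _keys(spr_neighbors(t))
        tbr = _keys(tbr_neighbors(t))
        assert spr <= tbr
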