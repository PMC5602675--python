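import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from conftest import (brute_force_char_steps, random_binary_matrix,
                      random_column_matrix)
from mosaweak.matrix_io import CharacterMatrix, CharacterSettings, parse_tnt
from mosaweak.parsimony import (RIUndefinedError, TreeScorer, char_steps,
                                ensemble_indices, iw_score, max_steps,
                                min_steps, tree_length)
from mosaweak.search import enumerate_unrooted_trees, exhaustive_search
from mosaweak.tree import Tree, TreeError


class TestCharSteps:
    def test_single_change(self, quartet):
        m = parse_tnt("xread 1 4 A 0 B 0 C 1 D 1 ;")
        assert char_steps(quartet, m, 1) == 1

    def test_ordered_additive_cost(self, quartet):
        m = parse_tnt("xread 1 4 A 0 B 0 C 2 D 2 ;")
        assert char_steps(quartet, m, 1, ordered=False) == 1
        assert char_steps(quartet, m, 1, ordered=True) == 2

    def test_missing_leaf_errors(self, quartet):
        m = parse_tnt("xread 1 3 A 0 B 0 C 1 ;")
        with pytest.raises(TreeError):
            char_steps(quartet, m, 1)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        taxa6 = [chr(65 + i) for i in range(6)]
        trees = list(enumerate_unrooted_trees(taxa6))
        for trial in range(25):
            m = random_column_matrix(rng, 6, 3)
            t = trees[rng.integers(len(trees))]
            for ordered in (False, True):
                got = char_steps(t, m, 1, ordered=ordered)
                want = brute_force_char_steps(t, m, 0, ordered)
                assert got == want, (trial, ordered)

    def test_polytomy_scoring_matches_brute_force(self):
        rng = np.random.default_rng(5)
        t = Tree.from_newick("((A,B,C),(D,E),F);")
        for _ in range(10):
            m = random_column_matrix(rng, 6, 3)
            for ordered in (False, True):
                got = char_steps(t, m, 1, ordered=ordered)
                assert got == brute_force_char_steps(t, m, 0, ordered)


class TestTreeLength:
    def test_all_constant_zero(self, quartet):
        m = parse_tnt("xread 2 4 A 00 B 00 C 00 D 00 ;")
        assert tree_length(quartet, m).total_length == 0

    def test_weighted_sum(self, quartet):
        m = parse_tnt("xread 2 4 A 00 B 01 C 10 D 11 ;")
        m.weight = [2.0, 3.0]
        bd = tree_length(quartet, m)
        expected = 2.0 * bd.per_char_steps[0] + 3.0 * bd.per_char_steps[1]
        assert bd.total_length == expected

    def test_bounds_bracket_steps(self):
        rng = np.random.default_rng(3)
        taxa = [chr(65 + i) for i in range(6)]
        trees = list(enumerate_unrooted_trees(taxa))
        m = random_binary_matrix(rng, 6, 12, k=3)
        t = trees[rng.integers(len(trees))]
        bd = tree_length(t, m)
        assert np.all(bd.per_char_min <= bd.per_char_steps)
        assert np.all(bd.per_char_steps <= bd.per_char_max)

    def test_length_invariant_under_rerooting(self):
        rng = np.random.default_rng(11)
        m = random_binary_matrix(rng, 6, 10, k=3)
        t1 = Tree.from_newick("((A,(B,C)),((D,E),F));")
        t2 = Tree.from_newick("(B,(C,(A,((D,E),F))));")  # same unrooted tree
        assert t1.bipartitions() == t2.bipartitions()
        assert tree_length(t1, m).total_length == tree_length(t2, m).total_length

    def test_ordered_never_cheaper(self):
        rng = np.random.default_rng(17)
        taxa = [chr(65 + i) for i in range(6)]
        trees = list(enumerate_unrooted_trees(taxa))
        for _ in range(10):
            m = random_column_matrix(rng, 6, 4)
            t = trees[rng.integers(len(trees))]
            assert char_steps(t, m, 1, ordered=True) >= char_steps(t, m, 1)


class TestBounds:
    def test_min_steps_unordered_cover(self):
        col = [frozenset({0}), frozenset({1}), frozenset({2})]
        assert min_steps(col, 3, ordered=False) == 2
        col = [frozenset({0, 1}), frozenset({1, 2}), frozenset({0, 2})]
        assert min_steps(col, 3, ordered=False) == 1

    def test_min_steps_ordered_range(self):
        col = [frozenset({0}), frozenset({3})]
        assert min_steps(col, 4, ordered=True) == 3
        col = [frozenset({0, 1, 2, 3}), frozenset({2})]
        assert min_steps(col, 4, ordered=True) == 0

    def test_max_steps_star(self):
        col = [frozenset({0}), frozenset({0}), frozenset({1}), frozenset({1}),
               frozenset({1})]
        assert max_steps(col, 2, ordered=False) == 2

    def test_full_ambiguity_contributes_nothing(self):
        col = [frozenset({0}), frozenset({1}), frozenset({0, 1})]
        assert min_steps(col, 2, ordered=False) == 1
        assert max_steps(col, 2, ordered=False) == 1

    def test_min_steps_attained_on_best_tree(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            m = random_column_matrix(rng, 6, 3, allow_ambiguity=False)
            for ordered in (False, True):
                st = CharacterSettings(
                    ordered_set=frozenset([1]) if ordered else frozenset())
                res = exhaustive_search(m, st)
                want = min_steps(m.column(0), 3, ordered)
                assert res.best_score == want


class TestEnsembleIndices:
    def test_no_homoplasy_gives_unity(self):
        m = parse_tnt("xread 2 4 A 00 B 01 C 10 D 11 ;")
        # optimal length = sum of minima = 2
        ci, ri = ensemble_indices(2, m)
        assert ci == 1.0 and ri == 1.0

    def test_ri_undefined_signal(self):
        # two-state character present in a single taxon: min == max
        m = parse_tnt("xread 1 4 A 1 B 0 C 0 D 0 ;")
        with pytest.raises(RIUndefinedError):
            ensemble_indices(1, m)

    def test_nonpositive_length_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            ensemble_indices(0, toy_matrix)


class TestImpliedWeighting:
    def test_homoplasy_free_distortion_zero(self, quartet):
        m = parse_tnt("xread 1 4 A 0 B 0 C 1 D 1 ;")
        s = CharacterSettings(weighting="IMPLIED", K=3.0)
        assert iw_score(quartet, m, s) == 0.0

    def test_single_character_arithmetic(self):
        # force h = 3 extra steps at K = 3 -> contribution 0.5
        t = Tree.from_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        m = parse_tnt("xread 1 8 A 0 B 1 C 0 D 1 E 0 F 1 G 0 H 1 ;")
        bd = tree_length(t, m)
        h = int(bd.per_char_steps[0] - bd.per_char_min[0])
        assert h == 3
        s = CharacterSettings(weighting="IMPLIED", K=3.0)
        assert iw_score(t, m, s) == pytest.approx(3 / (3 + 3))

    def test_iw_optimum_matches_brute_force(self):
        rng = np.random.default_rng(31)
        for K in (3.0, 6.0, 9.0):
            m = random_binary_matrix(rng, 6, 10, k=3)
            s = CharacterSettings(weighting="IMPLIED", K=K)
            ex = exhaustive_search(m, s)
            scorer = TreeScorer(m, s)
            taxa = list(m.taxa)
            best = min(scorer.distortion(t)
                       for t in enumerate_unrooted_trees(taxa))
            assert ex.best_score == pytest.approx(best, abs=1e-8)

    def test_large_K_ranking_approaches_length_ranking(self):
        rng = np.random.default_rng(37)
        m = random_binary_matrix(rng, 6, 12, k=3)
        taxa = list(m.taxa)
        trees = list(enumerate_unrooted_trees(taxa))
        lengths = [TreeScorer(m).length(t) for t in trees]
        sK = CharacterSettings(weighting="IMPLIED", K=1e7)
        dists = [TreeScorer(m, sK).distortion(t) for t in trees]
        for i in range(0, len(trees) - 1, 7):
            j = i + 1
            if lengths[i] != lengths[j]:
                assert (lengths[i] < lengths[j]) == (dists[i] < dists[j])


@hyp_settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_fitch_equals_sankoff_route(seed):
    """The bit-parallel Fitch fast path agrees with the Sankoff DP."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 8))
    m = random_binary_matrix(rng, n, 6, k=int(rng.integers(2, 5)))
    from mosaweak.search import random_addition_tree
    t = random_addition_tree(m, None, seed=seed)
    scorer = TreeScorer(m)
    fast = scorer.per_char_steps(t)
    slow = np.array([brute_force_char_steps(t, m, j, False)
                     for j in range(m.n_char)])
    assert np.array_equal(fast, slow)
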