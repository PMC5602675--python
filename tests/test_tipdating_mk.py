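import itertools

import numpy as np
import pytest

from mosaweak.matrix_io import CharacterMatrix
from mosaweak.tipdating import MkModel, gamma_category_rates, mk_log_likelihood
from mosaweak.tree import Node, Tree


def single_char_matrix(taxa, states, k):
    return CharacterMatrix(taxa=list(taxa),
                           cells=[[frozenset([s])] for s in states],
                           n_char=1, state_count=[k])


def ptrans(k, nu):
    e = np.exp(-k * nu / (k - 1))
    P = np.full((k, k), (1 - e) / k)
    P += np.eye(k) * e
    return P


def enumeration_loglik(tree, matrix, k, rate=1.0):
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    nodes = list(tree.postorder())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = {id(nd): s for nd, s in zip(internal, assign)}
        p = 1.0 / k
        for nd in nodes:
            if nd.parent is None:
                continue
            P = ptrans(k, nd.length * rate)
            if nd.is_leaf():
                cell = matrix.cells[idx[nd.label]][0]
                p *= sum(P[st[id(nd.parent)], s] for s in cell)
            else:
                p *= P[st[id(nd.parent)], st[id(nd)]]
        total += p
    return np.log(total)


class TestClosedForms:
    def test_two_tip_binary_different_states(self):
        nu = 0.9
        t = Tree.from_newick(f"(A:{nu*0.4},B:{nu*0.6});")
        m = single_char_matrix("AB", [0, 1], 2)
        ll = mk_log_likelihood(t, m, MkModel(n_gamma=1,
                                             condition_on_variable=False))
        want = np.log(0.5 * 0.5 * (1 - np.exp(-2 * nu)))
        assert ll == pytest.approx(want, abs=1e-12)

    def test_saturation_limit(self):
        # nu -> inf: tips become independent uniform draws, so every
        # pattern tends to sum_root (1/k) * (1/k)^n_tips = (1/k)^n_tips
        t = Tree.from_newick("((A:500,B:500):500,(C:500,D:500):500);")
        for k in (2, 3):
            m = single_char_matrix("ABCD", [0, 1 % k, 1, 0], k)
            ll = mk_log_likelihood(t, m, MkModel(n_gamma=1,
                                                 condition_on_variable=False))
            want = np.log((1 / k) ** 4)
            assert ll == pytest.approx(want, abs=1e-6)

    def test_state_relabeling_invariance(self):
        t = Tree.from_newick("((A:0.2,B:0.7):0.4,(C:0.3,D:0.1):0.2);")
        m1 = single_char_matrix("ABCD", [0, 1, 2, 0], 3)
        m2 = single_char_matrix("ABCD", [2, 0, 1, 2], 3)  # permuted states
        model = MkModel(n_gamma=4, gamma_shape=0.7)
        assert mk_log_likelihood(t, m1, model) == pytest.approx(
            mk_log_likelihood(t, m2, model), abs=1e-12)


class TestEnumerationOracle:
    def test_four_taxon_three_state(self):
        rng = np.random.default_rng(1)
        t = Tree.from_newick("((A:0.2,B:0.5):0.3,(C:0.1,D:0.4):0.6);")
        for _ in range(5):
            states = [int(rng.integers(3)) for _ in range(4)]
            m = single_char_matrix("ABCD", states, 3)
            ll = mk_log_likelihood(t, m, MkModel(n_gamma=1,
                                                 condition_on_variable=False))
            assert ll == pytest.approx(enumeration_loglik(t, m, 3), abs=1e-10)

    def test_ambiguity_as_partial_likelihood(self):
        t = Tree.from_newick("((A:0.2,B:0.5):0.3,(C:0.1,D:0.4):0.6);")
        m = CharacterMatrix(taxa=list("ABCD"),
                            cells=[[frozenset([0, 1])], [frozenset([1])],
                                   [frozenset([0])], [frozenset([2])]],
                            n_char=1, state_count=[3])
        ll = mk_log_likelihood(t, m, MkModel(n_gamma=1,
                                             condition_on_variable=False))
        assert ll == pytest.approx(enumeration_loglik(t, m, 3), abs=1e-10)

    def test_gamma_mixture_averages_categories(self):
        t = Tree.from_newick("((A:0.2,B:0.5):0.3,(C:0.1,D:0.4):0.6);")
        m = single_char_matrix("ABCD", [0, 1, 1, 0], 2)
        shape, ncat = 0.6, 4
        rates = gamma_category_rates(shape, ncat)
        want = np.log(np.mean([
            np.exp(enumeration_loglik(t, m, 2, rate=r)) for r in rates]))
        ll = mk_log_likelihood(t, m, MkModel(gamma_shape=shape, n_gamma=ncat,
                                             condition_on_variable=False))
        assert ll == pytest.approx(want, abs=1e-10)


class TestVariableConditioning:
    def test_conditioning_divides_by_variable_probability(self):
        t = Tree.from_newick("((A:0.2,B:0.5):0.3,(C:0.1,D:0.4):0.6);")
        m = single_char_matrix("ABCD", [0, 1, 1, 0], 2)
        raw = mk_log_likelihood(t, m, MkModel(n_gamma=1,
                                              condition_on_variable=False))
        cond = mk_log_likelihood(t, m, MkModel(n_gamma=1,
                                               condition_on_variable=True))
        p_const = sum(np.exp(enumeration_loglik(
            t, single_char_matrix("ABCD", [s] * 4, 2), 2)) for s in range(2))
        assert cond == pytest.approx(raw - np.log1p(-p_const), abs=1e-10)

    def test_conditioned_variable_likelihoods_sum_to_one(self):
        t = Tree.from_newick("((A:0.4,B:0.3):0.2,(C:0.5,D:0.1):0.3);")
        total = 0.0
        for states in itertools.product(range(2), repeat=4):
            if len(set(states)) == 1:
                continue
            m = single_char_matrix("ABCD", list(states), 2)
            total += np.exp(mk_log_likelihood(
                t, m, MkModel(n_gamma=1, condition_on_variable=True)))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestSampledAncestors:
    def test_sa_zero_length_equals_terminal_representation(self):
        # an SA with its observation at an internal node equals the same
        # tree written with a zero-length terminal attachment
        root = Node()
        root.age = 3.0
        sa = root.add_child(Node("X"))
        sa.age = 2.0
        sa.sampled_ancestor = True
        y = sa.add_child(Node("Y"))
        y.age = 0.5
        z = root.add_child(Node("Z"))
        z.age = 1.0
        t_sa = Tree(root)
        t_sa.set_lengths_from_ages()
        t_leaf = Tree.from_newick("((Y:1.5,X:0.0):1.0,Z:2.0);")
        m = CharacterMatrix(taxa=["X", "Y", "Z"],
                            cells=[[frozenset([0])], [frozenset([1])],
                                   [frozenset([1])]],
                            n_char=1, state_count=[2])
        model = MkModel(n_gamma=1, condition_on_variable=False)
        assert mk_log_likelihood(t_sa, m, model) == pytest.approx(
            mk_log_likelihood(t_leaf, m, model), abs=1e-12)


class TestErrors:
    def test_negative_branch_rejected(self):
        t = Tree.from_newick("(A:0.5,B:-0.1);")
        m = single_char_matrix("AB", [0, 1], 2)
        with pytest.raises(ValueError):
            mk_log_likelihood(t, m, MkModel())

    def test_gamma_rates_mean_one(self):
        for shape in (0.2, 1.0, 5.0):
            rates = gamma_category_rates(shape, 4)
            assert rates.mean() == pytest.approx(1.0)
            assert np.all(np.diff(rates) > 0)
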