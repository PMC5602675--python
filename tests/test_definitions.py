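import itertools

import pytest

from mosaweak.definitions import (APPLIES, NOT_EVALUABLE, SELF_DESTRUCTS,
                                  DefinitionOutcome, PhyloDefinition, ProxyMap,
                                  Specifier, evaluate_branch_based,
                                  evaluate_definition, evaluate_node_based,
                                  resolve_specifiers, weak_spot_report)
from mosaweak.tree import Node, Tree


def T(text):
    return Tree.from_newick(text)


def node_def(name, internal, external=()):
    return PhyloDefinition(name=name, kind="NODE",
                           internal=[Specifier(taxon=t) for t in internal],
                           external=[Specifier(taxon=t) for t in external])


def branch_def(name, internal, external=()):
    return PhyloDefinition(name=name, kind="BRANCH",
                           internal=[Specifier(taxon=t) for t in internal],
                           external=[Specifier(taxon=t) for t in external])


class TestResolve:
    def test_verbatim_leaf(self):
        d = node_def("X", ["A", "B"])
        internal, external, unresolved = resolve_specifiers(d, T("((A,B),C);"))
        assert internal == [frozenset({"A"}), frozenset({"B"})]
        assert unresolved == []

    def test_proxy_map_species_to_otu(self):
        d = node_def("X", ["Plioplatecarpus marshii", "Mosasaurus hoffmannii"])
        tree = T("(('Plioplatecarpus spp.','Mosasaurus hoffmannii'),Out);")
        pm = ProxyMap({"Plioplatecarpus marshii": "Plioplatecarpus spp."})
        internal, _, unresolved = resolve_specifiers(d, tree, pm)
        assert internal[0] == frozenset({"Plioplatecarpus spp."})
        assert unresolved == []

    def test_genus_fallback_unique_only(self):
        pm = ProxyMap()
        otus = ["Tylosaurus proriger", "Globidens alabamaensis",
                "Globidens dakotensis"]
        assert pm.resolve("Tylosaurus bernardi", otus) == "Tylosaurus proriger"
        assert pm.resolve("Globidens schurmanni", otus) is None  # ambiguous

    def test_composite_resolves_to_mrca(self):
        d = PhyloDefinition(
            name="X", kind="BRANCH", internal=[Specifier(taxon="A")],
            external=[Specifier(node_of=("C", "D"))])
        tree = T("((A,B),(C,(D,E)));")
        _, external, unresolved = resolve_specifiers(d, tree)
        assert external[0] == frozenset({"C", "D", "E"})
        assert unresolved == []

    def test_unresolvable_internal_not_evaluable(self):
        d = node_def("X", ["A", "Zed zed"])
        out = evaluate_node_based(d, T("((A,B),C);"))
        assert out.status == NOT_EVALUABLE
        assert "Zed zed" in out.reason


class TestNodeBased:
    def test_applies(self):
        d = node_def("X", ["A", "B"], external=["C"])
        out = evaluate_node_based(d, T("((A,B),(C,D));"))
        assert out.status == APPLIES
        assert out.clade == frozenset({"A", "B"})

    def test_self_destructs_when_external_intrudes(self):
        d = node_def("X", ["A", "B"], external=["C"])
        out = evaluate_node_based(d, T("((A,C),(B,D));"))
        assert out.status == SELF_DESTRUCTS

    def test_polytomy_mrca_includes_all_children(self):
        d = node_def("X", ["A", "B"])
        out = evaluate_node_based(d, T("((A,B,E),(C,D));"))
        assert out.clade == frozenset({"A", "B", "E"})


class TestBranchBased:
    def test_walk_rootward(self):
        d = branch_def("X", ["A"], external=["C"])
        out = evaluate_branch_based(d, T("((A,B),(C,D));"))
        assert out.status == APPLIES
        assert out.clade == frozenset({"A", "B"})

    def test_walk_stops_immediately(self):
        d = branch_def("X", ["A"], external=["C"])
        out = evaluate_branch_based(d, T("((A,C),B);"))
        assert out.clade == frozenset({"A"})

    def test_self_destructs_if_external_inside_mrca(self):
        d = branch_def("X", ["A", "B"], external=["C"])
        out = evaluate_branch_based(d, T("(((A,C),B),D);"))
        assert out.status == SELF_DESTRUCTS

    def test_branch_contains_node_clade(self):
        # whenever both apply, the branch-based clade contains the node-based
        trees = ["((A,B),(C,(D,E)));", "(((A,B),C),(D,E));",
                 "((((A,B),C),D),E);"]
        nd = node_def("N", ["A", "B"], external=["E"])
        bd = branch_def("B", ["A", "B"], external=["E"])
        for text in trees:
            no = evaluate_node_based(nd, T(text))
            bo = evaluate_branch_based(bd, T(text))
            if no.status == APPLIES and bo.status == APPLIES:
                assert no.clade <= bo.clade


def _all_rooted_trees(labels):
    """Every rooted binary topology over the given labels: (2n-3)!! trees."""
    if len(labels) == 1:
        yield Node(labels[0])
        return
    first, rest = labels[0], labels[1:]
    for sub in _all_rooted_trees(rest):
        base = Tree(sub)
        n_nodes = sum(1 for _ in base.postorder())
        for i in range(n_nodes):
            t = base.copy()
            target = list(t.postorder())[i]
            joint = Node()
            if target.parent is None:
                joint.add_child(t.root)
                joint.add_child(Node(first))
                yield joint
            else:
                p = target.parent
                idx = p.children.index(target)
                p.children[idx] = joint
                joint.parent = p
                joint.add_child(target)
                joint.add_child(Node(first))
                yield t.root


class TestBruteForceSixLeaves:
    def test_evaluator_matches_predicate_enumeration(self):
        labels = ["A", "B", "C", "D", "E", "F"]
        nd = node_def("N", ["A", "B"], external=["C"])
        bd = branch_def("B", ["A", "B"], external=["C"])
        count = 0
        for root in _all_rooted_trees(labels):
            tree = Tree(root)
            count += 1
            clades = {c for c in tree.clades()} | \
                {frozenset([lf]) for lf in labels}
            # predicate: least inclusive clade containing A and B
            containing = [c for c in clades if {"A", "B"} <= c]
            mrca = min(containing, key=len)
            if "C" in mrca:
                expect_node = expect_branch = SELF_DESTRUCTS
                node_clade = branch_clade = None
            else:
                expect_node = expect_branch = APPLIES
                node_clade = mrca
                eligible = [c for c in clades
                            if {"A", "B"} <= c and "C" not in c]
                branch_clade = max(eligible, key=len)
            no = evaluate_node_based(nd, tree)
            bo = evaluate_branch_based(bd, tree)
            assert no.status == expect_node
            assert bo.status == expect_branch
            assert no.clade == node_clade
            assert bo.clade == branch_clade
        assert count == 945  # (2*6-3)!! rooted binary topologies

    def test_rotation_invariance(self):
        d = branch_def("X", ["A"], external=["C"])
        t1 = T("((A,B),(C,D));")
        t2 = T("((B,A),(D,C));")
        assert evaluate_branch_based(d, t1).clade == \
            evaluate_branch_based(d, t2).clade


class TestWeakSpotReport:
    def test_single_run_degenerate(self):
        d = node_def("N", ["A", "B"], external=["C"])
        report = weak_spot_report([d], {"only": T("((A,B),C);")})
        assert report.status[("N", "only")].status == APPLIES
        assert report.summary["N"] == "CONSISTENT"

    def test_classification(self):
        d = node_def("N", ["A", "B"], external=["C"])
        runs = {"good": T("((A,B),(C,D));"), "bad": T("((A,C),(B,D));")}
        report = weak_spot_report([d], runs)
        assert report.summary["N"] == "STRATEGY_DEPENDENT"
        rows = report.to_rows()
        assert len(rows) == 2

    def test_applies_fraction_over_optima(self):
        d = node_def("N", ["A", "B"], external=["C"])
        trees = [T("((A,B),(C,D));"), T("((A,C),(B,D));"),
                 T("((A,B),(C,D));")]
        runs = {"r": {"consensus": T("(A,B,C,D);"), "trees": trees}}
        report = weak_spot_report([d], runs)
        assert report.applies_fraction[("N", "r")] == pytest.approx(2 / 3)


class TestOutcomeInvariants:
    def test_clade_iff_applies(self):
        with pytest.raises(ValueError):
            DefinitionOutcome(status=APPLIES, clade=None)
        with pytest.raises(ValueError):
            DefinitionOutcome(status=SELF_DESTRUCTS,
                              clade=frozenset({"A"}))

    def test_definition_validation(self):
        with pytest.raises(ValueError):
            PhyloDefinition(name="X", kind="NODE",
                            internal=[Specifier(taxon="A")])
        with pytest.raises(ValueError):
            PhyloDefinition(name="X", kind="BRANCH", internal=[])
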