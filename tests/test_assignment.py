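"""Node truth thresholds, the four sub-algorithms, and the full pipeline."""

import numpy as np
import pytest

from amytree.assignment import (
    AssignParams,
    NodeStatus,
    Truth,
    assign,
    combine,
    compute_node_statuses,
    horizontal_descend,
    most_specific,
    node_truth,
    to_mutation_nomenclature,
    vertical_scan,
)
from amytree.core_model import HaplogroupNode, MarkerDef, MarkerTable, PhyloTree
from amytree.marker_status import CALLED, REFERENCE, AlleleState, StatusTable
from amytree.synthetic_fixtures import (
    SimSpec,
    brute_combine,
    brute_horizontal,
    brute_specific,
    brute_vertical,
    make_fixture,
    random_statuses,
    random_tree,
    simulate_profile,
)


def _node(marker_names):
    return HaplogroupNode(name="N", parent=HaplogroupNode(name="R"),
                          defining_markers=tuple(marker_names))


def _states(n_mutant, n_ancestral, n_ref_mutant=0, n_other=0):
    """StatusTable with the requested composition; returns (node, table)."""
    table = StatusTable("hg19")
    names = []
    i = 0
    for count, state, prov in [(n_mutant, 1, CALLED), (n_ancestral, 0, CALLED),
                               (n_ref_mutant, 1, REFERENCE), (n_other, -1, CALLED)]:
        for _ in range(count):
            i += 1
            name = f"S{i}"
            table.add(AlleleState(name, state, prov))
            names.append(name)
    return _node(names), table


class TestNodeTruth:
    def test_sufficient_regime_hand_examples(self):
        # 6 of 7 mutant = 85.7% > 85% -> true; 5 of 7 = 71.4% -> false
        node, table = _states(6, 1)
        assert node_truth(node, table, sufficient=True).truth is Truth.TRUE
        node, table = _states(5, 2)
        assert node_truth(node, table, sufficient=True).truth is Truth.FALSE

    def test_insufficient_regime_reference_mutants_dropped(self):
        # 10 markers: 2 mutant-by-reference (dropped from both sides),
        # 1 mutant-by-call, 7 ancestral -> 1/8 = 12.5% > 5% -> true
        node, table = _states(1, 7, n_ref_mutant=2)
        status = node_truth(node, table, sufficient=False)
        assert status.n_used == 8
        assert status.pct_mutant == pytest.approx(0.125)
        assert status.truth is Truth.TRUE

    def test_reference_mutants_count_in_sufficient_regime(self):
        node, table = _states(1, 7, n_ref_mutant=2)
        status = node_truth(node, table, sufficient=True)
        assert status.n_used == 10
        assert status.pct_mutant == pytest.approx(0.3)

    def test_thresholds_are_strict(self):
        # exactly 85.0% (17/20) and exactly 5.0% (1/20) are false
        node, table = _states(17, 3)
        assert node_truth(node, table, sufficient=True).truth is Truth.FALSE
        node, table = _states(18, 2)  # 90% > 85%
        assert node_truth(node, table, sufficient=True).truth is Truth.TRUE
        node, table = _states(1, 19)
        assert node_truth(node, table, sufficient=False).truth is Truth.FALSE
        node, table = _states(2, 18)  # 10% > 5%
        assert node_truth(node, table, sufficient=False).truth is Truth.TRUE

    def test_other_states_leave_denominator(self):
        node, table = _states(6, 1, n_other=3)
        assert node_truth(node, table, sufficient=True).n_used == 7

    def test_no_usable_markers_is_indeterminate(self):
        # e.g. every defining marker is an indel and was excluded upstream
        node = _node(["GONE1", "GONE2"])
        status = node_truth(node, StatusTable("hg19"), sufficient=True)
        assert status.truth is Truth.INDETERMINATE and status.pct_mutant is None

    def test_paragroup_uses_parent_markers(self):
        parent = HaplogroupNode(name="Z2b", defining_markers=("S1",))
        star = HaplogroupNode(name="Z2b*", parent=parent)
        parent.children.append(star)
        table = StatusTable("hg19")
        table.add(AlleleState("S1", 1, CALLED))
        assert node_truth(star, table, sufficient=True).truth is Truth.TRUE


def _walkthrough_statuses(walkthrough):
    from amytree.marker_status import build_status_table
    states = build_status_table(walkthrough.markers, walkthrough.profile, walkthrough.reference)
    return compute_node_statuses(walkthrough.tree, states, sufficient=True,
                                 markers=walkthrough.markers)


class TestSubAlgorithmsOnPackagedFixture:
    def test_vertical(self, walkthrough):
        statuses = _walkthrough_statuses(walkthrough)
        assert vertical_scan(walkthrough.tree, statuses) == {"X1a", "Z2b*", "Z2b3a"}

    def test_horizontal(self, walkthrough):
        statuses = _walkthrough_statuses(walkthrough)
        assert horizontal_descend(walkthrough.tree, statuses) == {"Z2b"}

    def test_combinatorial_drops_leaf_without_horizontal_ancestor(self, walkthrough):
        assert combine({"X1a", "Z2b*", "Z2b3a"}, {"Z2b"}, walkthrough.tree) == {"Z2b*", "Z2b3a"}

    def test_specific_resolves_paragroup_to_named_subclade(self, walkthrough):
        assert most_specific({"Z2b*", "Z2b3a"}, walkthrough.tree) == {"Z2b3a"}

    def test_all_false_edge_cases(self, walkthrough):
        statuses = {n.name: NodeStatus(n.name, Truth.FALSE, 0.0, 1)
                    for n in walkthrough.tree.nodes()}
        assert vertical_scan(walkthrough.tree, statuses) == set()
        assert horizontal_descend(walkthrough.tree, statuses) == set()
        assert combine(set(), set(), walkthrough.tree) == set()

    def test_singleton_and_incomparable_specific(self, walkthrough):
        assert most_specific({"X1a"}, walkthrough.tree) == {"X1a"}
        assert most_specific({"X1a", "Z2b3a"}, walkthrough.tree) == {"X1a", "Z2b3a"}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_traversals_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(30):
            tree = random_tree(rng)
            statuses = random_statuses(rng, tree)
            vertical = vertical_scan(tree, statuses)
            horizontal = horizontal_descend(tree, statuses)
            assert vertical == brute_vertical(tree, statuses)
            assert horizontal == brute_horizontal(tree, statuses)
            combinatorial = combine(vertical, horizontal, tree)
            assert combinatorial == brute_combine(vertical, horizontal, tree)
            assert most_specific(combinatorial, tree) == brute_specific(combinatorial, tree)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_chain_and_ancestor_invariants(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(30):
            tree = random_tree(rng)
            statuses = random_statuses(rng, tree)
            vertical = vertical_scan(tree, statuses)
            horizontal = horizontal_descend(tree, statuses)
            combinatorial = combine(vertical, horizontal, tree)
            specific = most_specific(combinatorial, tree)
            assert specific <= combinatorial <= vertical
            for name in horizontal:
                for anc in tree.ancestors(name)[1:]:
                    assert statuses[anc].truth in (Truth.TRUE, Truth.INDETERMINATE)


class TestMutationNomenclature:
    def test_paragroup_with_parent_marker(self):
        parent = HaplogroupNode(name="R1b1b2a2", defining_markers=("P312",))
        root = HaplogroupNode(name="Root", children=[parent])
        parent.parent = root
        star = HaplogroupNode(name="R1b1b2a2*", parent=parent)
        parent.children.append(star)
        markers = MarkerTable([MarkerDef(name="P312", pos_hg19=1, ancestral="A", mutant="C")])
        assert to_mutation_nomenclature(star, markers) == "R-P312*"

    def test_named_haplogroup(self):
        root = HaplogroupNode(name="Root")
        node = HaplogroupNode(name="I1*", parent=root, defining_markers=("M253",))
        root.children.append(node)
        markers = MarkerTable([MarkerDef(name="M253", pos_hg19=1, ancestral="A", mutant="C")])
        assert to_mutation_nomenclature(node, markers) == "I-M253*"

    def test_root_keeps_its_label(self, walkthrough):
        assert to_mutation_nomenclature(walkthrough.tree.root, walkthrough.markers) == "Root"

    def test_unresolvable_marker(self):
        root = HaplogroupNode(name="Root")
        node = HaplogroupNode(name="Q1", parent=root)
        root.children.append(node)
        assert to_mutation_nomenclature(node, MarkerTable()) == "Q-?"


class TestAssignPipeline:
    def test_packaged_fixture_final_call(self, walkthrough):
        result = assign(walkthrough.profile, walkthrough.tree, walkthrough.markers, walkthrough.reference)
        assert result.quality.sufficient
        assert result.final_alphanumeric == ["Z2b3a"]
        assert result.final_mutation_based == ["Z-M325"]
        assert result.specific <= result.combinatorial <= result.vertical

    def test_zero_error_leaf_recovery_small_fixture(self):
        # one reference lineage per depth-2 subtree keeps expected calls high
        # enough that every leaf's profile passes the quality gate
        fx = make_fixture(SimSpec(n_levels=3, branching=2, markers_per_branch=2,
                                  reference_lineages=4, seed=5))
        for leaf in (l.name for l in fx.tree.leaves()):
            profile = simulate_profile(fx, leaf, fp_rate=0, fn_rate=0, seed=1)
            result = assign(profile, fx.tree, fx.markers, fx.reference)
            assert result.final_alphanumeric == [leaf]

    def test_empty_horizontal_falls_back_to_vertical(self, recovery_fixture):
        fx = recovery_fixture
        leaf = fx.tree.leaves()[3].name
        profile = simulate_profile(fx, leaf, fp_rate=0, fn_rate=0.9, seed=2)
        result = assign(profile, fx.tree, fx.markers, fx.reference)
        assert not result.quality.sufficient
        assert result.horizontal == set()
        assert any("vertical" in w for w in result.warnings)
        assert any("caution" in w for w in result.warnings)

    def test_insufficient_regime_can_return_incompatible_leaves(self, walkthrough):
        # engineered statuses: two incompatible leaves true under the lax regime
        from amytree.core_model import SnpProfile, SnpCall
        profile = SnpProfile("hg19", [
            SnpCall(200, "G", "A"),   # X1a mutant
            SnpCall(350, "C", "G"),   # Z1 mutant
        ], sample_id="lowcov")
        result = assign(profile, walkthrough.tree, walkthrough.markers, walkthrough.reference)
        assert not result.quality.sufficient
        assert {"X1a", "Z1"} <= result.vertical
        assert set(result.final_alphanumeric) == {"X1a", "Z1"}
        assert any("multiple incompatible" in w for w in result.warnings)
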