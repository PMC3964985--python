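"""Species-overlap labeling, seed-relative rooting, nodal distances, ages."""

import itertools

import numpy as np
import pytest

from _oracles import naive_nodal_distance
from phylomekit import simulate
from phylomekit.events import (
    LineageMap,
    assign_relative_ages,
    label_events,
    nodal_distance,
    root_tree,
)
from phylomekit.treeio import TreeError, parse_newick, parse_species_tree, write_newick


class TestLabelEvents:
    def test_duplication_at_root_of_two_cherries(self, two_by_two_tree):
        tree = label_events(two_by_two_tree)
        assert tree.root.event == "duplication"
        assert tree.root.overlap_score == 1.0
        for cherry in tree.root.children:
            assert cherry.event == "speciation"
            assert cherry.overlap_score == 0.0

    def test_all_speciations_without_overlap(self):
        tree = label_events(parse_newick("((A_HUMAN,B_MOUSE),C_YEAST);"))
        assert all(
            n.event == "speciation" for n in tree.root.traverse() if not n.is_leaf
        )

    def test_threshold_semantics_are_strict_inequality(self):
        # children species sets {HUMAN,MOUSE,RAT} and {HUMAN}: Jaccard 1/3
        tree = parse_newick("(((A_HUMAN,B_MOUSE),C_RAT),D_HUMAN);")
        label_events(tree, threshold=0.5)
        assert tree.root.overlap_score == pytest.approx(1 / 3)
        assert tree.root.event == "speciation"
        label_events(tree, threshold=0.0)
        assert tree.root.event == "duplication"
        # boundary: threshold equal to the score -> still speciation
        label_events(tree, threshold=1 / 3)
        assert tree.root.event == "speciation"

    def test_multifurcation_uses_max_pairwise_jaccard(self):
        tree = parse_newick("(A_HUMAN,(B_HUMAN,C_MOUSE,D_YEAST));")
        label_events(tree)
        assert tree.root.event == "duplication"
        assert tree.root.overlap_score == pytest.approx(1 / 3)
        assert tree.root.children[1].event == "speciation"

    def test_unrooted_input_rejected(self):
        tree = parse_newick("(A_HUMAN,B_MOUSE,C_YEAST);")
        with pytest.raises(TreeError, match="root_tree"):
            label_events(tree)

    def test_overlap_score_bounds_on_simulations(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            sp = simulate.simulate_species_tree(8, int(rng.integers(2**31)))
            rec = simulate.simulate_gene_family(
                sp, 0.6, 0.2, int(rng.integers(2**31))
            )
            tree = label_events(rec.gene_tree)
            for node in tree.root.traverse():
                if not node.is_leaf:
                    assert 0.0 <= node.overlap_score <= 1.0
                    assert (node.event == "duplication") == (
                        node.overlap_score > 0.0
                    )


class TestRootTree:
    def test_farthest_taxon_roots_on_outgroup_edge(self, simple_species_tree):
        tree = parse_newick("(A_HUMAN,B_MOUSE,C_YEAST);")
        rooted = root_tree(tree, simple_species_tree, "A_HUMAN")
        sides = [c.species_set() for c in rooted.root.children]
        assert frozenset({"YEAST"}) in sides
        assert frozenset({"HUMAN", "MOUSE"}) in sides

    def test_two_leaf_tree_rooted_on_single_edge(self, simple_species_tree):
        tree = parse_newick("(A_HUMAN,B_MOUSE);")
        for strategy in ("farthest_taxon", "midpoint"):
            rooted = root_tree(tree, simple_species_tree, "A_HUMAN", strategy)
            assert len(rooted.root.children) == 2

    def test_midpoint_halves_longest_path(self):
        # longest path B-C = 0.3 + 0.05 + 0.6 = 0.95; midpoint inside C's edge
        tree = parse_newick("((A_HUMAN:0.1,B_HUMAN:0.3):0.05,C_HUMAN:0.6);")
        rooted = root_tree(tree, strategy="midpoint")
        from phylomekit.events import branch_length_distance

        db = branch_length_distance(rooted, rooted.find_leaf("B_HUMAN"), rooted.find_leaf("C_HUMAN"))
        # distances from root to B and to C must both equal 0.475
        root_children = rooted.root.children
        depths = {}
        for leaf in rooted.leaves():
            d = leaf.branch_length or 0.0
            node = leaf.parent
            while node.parent is not None:
                d += node.branch_length or 0.0
                node = node.parent
            depths[leaf.name] = d
        assert depths["B_HUMAN"] == pytest.approx(0.475)
        assert depths["C_HUMAN"] == pytest.approx(0.475)

    def test_all_same_species_falls_back_to_midpoint(self, simple_species_tree):
        tree = parse_newick("((A_HUMAN:0.1,B_HUMAN:0.3):0.1,C_HUMAN:0.6);")
        rooted = root_tree(tree, simple_species_tree, "A_HUMAN")
        assert len(rooted.root.children) == 2

    def test_midpoint_without_lengths_errors(self):
        tree = parse_newick("((A_HUMAN,B_HUMAN),C_HUMAN);")
        with pytest.raises(TreeError, match="branch lengths"):
            root_tree(tree, strategy="midpoint")

    def test_species_missing_from_species_tree_is_an_error(
        self, simple_species_tree
    ):
        tree = parse_newick("(A_HUMAN,B_MOUSE,C_CANFA);")
        with pytest.raises(TreeError, match="CANFA"):
            root_tree(tree, simple_species_tree, "A_HUMAN")


class TestNodalDistance:
    def test_examples(self):
        tree = parse_newick("(((((a_A,b_B),c_C),d_D),e_E),f_F);")
        assert nodal_distance(tree, "a_A", "b_B") == 2
        assert nodal_distance(tree, "a_A", "a_A") == 0
        assert nodal_distance(tree, "a_A", "f_F") == 6

    def test_lookup_error(self):
        tree = parse_newick("(a_A,b_B);")
        with pytest.raises(TreeError):
            nodal_distance(tree, "a_A", "z_Z")

    def test_metric_properties_on_random_trees(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            labels = [f"g{i}_SP{i:02d}" for i in range(int(rng.integers(4, 10)))]
            tree = simulate.random_rooted_tree(labels, int(rng.integers(2**31)))
            leaves = tree.leaves()
            for a, b, c in itertools.islice(
                itertools.permutations(leaves, 3), 30
            ):
                dab = nodal_distance(tree, a, b)
                assert dab == nodal_distance(tree, b, a)  # symmetry
                assert dab > 0  # distinct leaves
                assert dab == naive_nodal_distance(a, b)
                assert dab <= nodal_distance(tree, a, c) + nodal_distance(
                    tree, c, b
                )  # triangle inequality


class TestRelativeAges:
    def test_lineage_levels_are_nested_and_increasing(self, primate_species_tree):
        lin = LineageMap.from_species_tree(primate_species_tree, "HUMAN")
        names = [lvl.name for lvl in lin.levels]
        assert names == ["HUMAN", "Primates", "Mammalia", "Eukaryota"]
        for a, b in zip(lin.levels, lin.levels[1:]):
            assert a.species < b.species  # strictly nested

    @pytest.mark.parametrize(
        "newick, expected_root_age",
        [
            ("((A_HUMAN,B_MOUSE),(C_HUMAN,D_MOUSE));", 2),  # Mammalia
            ("(A_HUMAN,B_HUMAN);", 0),  # seed species only
            ("(A_HUMAN,C_YEAST);", 3),  # Eukaryota
        ],
    )
    def test_age_examples(self, primate_species_tree, newick, expected_root_age):
        lin = LineageMap.from_species_tree(primate_species_tree, "HUMAN")
        tree = assign_relative_ages(parse_newick(newick), lin)
        assert tree.root.age_index == expected_root_age

    def test_species_outside_all_levels_is_an_error(self, primate_species_tree):
        lin = LineageMap.from_species_tree(primate_species_tree, "HUMAN")
        with pytest.raises(TreeError, match="CANFA"):
            assign_relative_ages(parse_newick("(A_HUMAN,B_CANFA);"), lin)

    def test_age_monotonicity_on_simulations(self, ):
        rng = np.random.default_rng(31)
        for _ in range(25):
            sp = simulate.simulate_species_tree(7, int(rng.integers(2**31)))
            rec = simulate.simulate_gene_family(
                sp, 0.5, 0.2, int(rng.integers(2**31))
            )
            tree = rec.gene_tree
            seed_species = tree.leaves()[0].species
            lin = LineageMap.from_species_tree(sp, seed_species)
            assign_relative_ages(tree, lin)
            for node in tree.root.traverse():
                if node.parent is not None:
                    assert node.age_index <= node.parent.age_index
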