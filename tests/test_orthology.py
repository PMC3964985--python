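"""Orthology inference, close2seed, consistency scores and exports."""

import io
import itertools

import numpy as np
import pytest

from _oracles import naive_nodal_distance, naive_ortholog_pairs
from phylomekit import simulate
from phylomekit.events import label_events
from phylomekit.orthology import (
    Close2SeedConfig,
    Gene,
    OrthologyCall,
    apply_close2seed,
    consistency_scores,
    infer_orthology,
    one_to_one_sets,
    parse_orthoxml,
    rank_leaves_by_seed_distance,
    write_orthoxml,
    write_tsv,
)
from phylomekit.treeio import TreeError, parse_newick


def _labeled(newick: str):
    return label_events(parse_newick(newick))


def _pairs(calls, relation="ortholog"):
    return {c.pair_key() for c in calls if c.relation == relation}


class TestInferOrthology:
    def test_seed_calls_in_duplicated_family(self, two_by_two_tree):
        calls = infer_orthology(label_events(two_by_two_tree), seed_leaf="H1_HUMAN")
        by_target = {str(c.gene_b): c for c in calls}
        assert by_target["M1_MOUSE"].relation == "ortholog"
        assert by_target["M1_MOUSE"].type == "one-to-one"
        assert by_target["H2_HUMAN"].relation == "paralog"
        assert by_target["M2_MOUSE"].relation == "paralog"

    def test_one_to_many_after_lineage_specific_duplication(self):
        calls = infer_orthology(
            _labeled("(H1_HUMAN,(M1_MOUSE,M2_MOUSE));"), seed_leaf="H1_HUMAN"
        )
        assert {(str(c.gene_b), c.relation, c.type) for c in calls} == {
            ("M1_MOUSE", "ortholog", "one-to-many"),
            ("M2_MOUSE", "ortholog", "one-to-many"),
        }

    def test_many_to_many_all_vs_all_enumeration(self):
        calls = infer_orthology(
            _labeled("((H1_HUMAN,H2_HUMAN),(M1_MOUSE,M2_MOUSE));"),
            all_vs_all=True,
        )
        assert len(calls) == 6  # partition property: one call per pair
        orthologs = [c for c in calls if c.relation == "ortholog"]
        paralogs = [c for c in calls if c.relation == "paralog"]
        assert len(orthologs) == 4 and len(paralogs) == 2
        assert all(c.type == "many-to-many" for c in orthologs)
        assert all(c.gene_a.species == c.gene_b.species for c in paralogs)

    def test_unlabeled_tree_rejected(self):
        with pytest.raises(TreeError, match="label_events"):
            infer_orthology(parse_newick("(A_HUMAN,B_MOUSE);"), seed_leaf="A_HUMAN")

    def test_symmetry_and_type_transposition(self):
        tree = _labeled("(H1_HUMAN,(M1_MOUSE,M2_MOUSE));")
        fwd = {
            c.pair_key(): c for c in infer_orthology(tree, seed_leaf="H1_HUMAN")
        }
        back = infer_orthology(tree, seed_leaf="M1_MOUSE")
        for call in back:
            if call.pair_key() in fwd:
                mirror = fwd[call.pair_key()]
                assert call.relation == mirror.relation
                assert call.swapped().type == mirror.type

    def test_matches_naive_lca_oracle_on_simulations(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            sp = simulate.simulate_species_tree(
                int(rng.integers(4, 10)), int(rng.integers(2**31))
            )
            rec = simulate.simulate_gene_family(
                sp, 0.7, 0.2, int(rng.integers(2**31)), min_leaves=3
            )
            tree = label_events(rec.gene_tree)
            calls = infer_orthology(tree, all_vs_all=True)
            got = {
                frozenset(((c.gene_a.seq_id, c.gene_a.species),
                           (c.gene_b.seq_id, c.gene_b.species)))
                for c in calls
                if c.relation == "ortholog"
            }
            assert got == naive_ortholog_pairs(tree)

    def test_ground_truth_recovery_loss_free(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sp = simulate.simulate_species_tree(8, int(rng.integers(2**31)))
            rec = simulate.simulate_gene_tree(sp, 0.5, 0.0, int(rng.integers(2**31)))
            tree = label_events(rec.gene_tree)
            assert _pairs(infer_orthology(tree, all_vs_all=True)) == (
                simulate.true_orthologs(rec)
            )


class TestClose2Seed:
    def test_filter_vacuous_when_k_exceeds_leaf_count(self):
        tree = _labeled(
            "((((g1_SPA,g2_SPB),(g3_SPC,g4_SPD)),((g5_SPE,g6_SPF),(g7_SPG,g8_SPH))),(g9_SPI,g10_SPJ));"
        )
        calls = infer_orthology(tree, seed_leaf="g1_SPA")
        kept = apply_close2seed(calls, tree, "g1_SPA", Close2SeedConfig(k=30))
        assert kept == calls

    def test_k1_keeps_only_seed_and_nearest_leaf(self):
        tree = _labeled("((S_HUMAN,M_MOUSE),(X_RAT,Y_CANFA));")
        calls = infer_orthology(tree, all_vs_all=True)
        kept = apply_close2seed(calls, tree, "S_HUMAN", Close2SeedConfig(k=1))
        allowed = {Gene("S", "HUMAN"), Gene("M", "MOUSE")}
        assert kept  # something survives
        for call in kept:
            assert call.gene_a in allowed or call.gene_b in allowed
        dropped = [c for c in calls if c not in kept]
        for call in dropped:
            assert call.gene_a not in allowed and call.gene_b not in allowed

    def test_caterpillar_brute_force_set_check(self):
        n = 40
        newick = "(a0_SP000,b0_SQ000)"
        for i in range(1, n):
            newick = f"({newick},x{i}_SP{i:03d})"
        tree = _labeled(newick + ";")
        seed = "a0_SP000"
        calls = infer_orthology(tree, all_vs_all=True)
        kept = apply_close2seed(calls, tree, seed, Close2SeedConfig(k=30))
        # brute-force ranking from explicitly enumerated path lengths
        seed_leaf = tree.find_leaf(seed)
        ranked = sorted(
            (l for l in tree.leaves() if l is not seed_leaf),
            key=lambda l: (naive_nodal_distance(seed_leaf, l), l.seq_id),
        )
        keep_genes = {Gene(seed_leaf.seq_id, seed_leaf.species)} | {
            Gene(l.seq_id, l.species) for l in ranked[:30]
        }
        expected = [
            c
            for c in calls
            if c.gene_a in keep_genes or c.gene_b in keep_genes
        ]
        assert kept == expected
        assert len(kept) < len(calls)  # ranks 31+ pairs actually dropped

    def test_k_monotonicity(self):
        labels = [f"g{i:02d}_SP{i:03d}" for i in range(20)]
        tree = label_events(simulate.random_rooted_tree(labels, 3))
        calls = infer_orthology(tree, all_vs_all=True)
        previous: set = set()
        for k in range(1, len(labels) + 1):
            kept = {
                (str(c.gene_a), str(c.gene_b))
                for c in apply_close2seed(
                    calls, tree, labels[0], Close2SeedConfig(k=k)
                )
            }
            assert previous <= kept
            previous = kept

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            Close2SeedConfig(k=0)

    def test_ranking_is_deterministic(self):
        tree = _labeled("((S_HUMAN,M_MOUSE),(X_RAT,Y_CANFA));")
        r1 = [l.name for l in rank_leaves_by_seed_distance(tree, "S_HUMAN")]
        r2 = [l.name for l in rank_leaves_by_seed_distance(tree, "S_HUMAN")]
        assert r1 == r2 == ["M_MOUSE", "X_RAT", "Y_CANFA"]


class TestConsistencyScores:
    def _trees(self):
        t_orth = "((H1_HUMAN,M1_MOUSE),C_YEAST);"  # H1-M1 speciation
        # H1 and M1 sit in different copies of a duplicated clade, so their
        # LCA is the duplication node
        t_para = "(((H1_HUMAN,M3_MOUSE),(H2_HUMAN,M1_MOUSE)),C_YEAST);"
        return [
            _labeled(t_orth),
            _labeled(t_orth.replace("C_YEAST", "D_YEAST")),
            _labeled(t_para),
            _labeled(t_para.replace("C_YEAST", "D_YEAST")),
        ]

    def test_fraction_of_trees_supporting_orthology(self):
        # H1-M1: orthologous in the 2 cherry trees, paralogous in the 2
        # duplicated trees (their LCA there is the duplication root)
        trees = self._trees()
        for t in trees[2:]:
            assert t.root.children[0].event == "duplication"
        calls = consistency_scores(
            trees, [(Gene("H1", "HUMAN"), Gene("M1", "MOUSE"))]
        )
        assert len(calls) == 1
        assert calls[0].n_trees == 4
        assert calls[0].consistency_score == pytest.approx(0.5)

    def test_single_tree_scores_are_binary(self):
        calls = consistency_scores(
            [_labeled("((H1_HUMAN,M1_MOUSE),C_YEAST);")]
        )
        assert calls
        assert all(c.consistency_score in (0.0, 1.0) for c in calls)
        assert all(c.n_trees == 1 for c in calls)

    def test_pair_never_cooccurring_is_omitted(self):
        calls = consistency_scores(
            self._trees(), [(Gene("H1", "HUMAN"), Gene("Z9", "YEAST"))]
        )
        assert calls == []

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            consistency_scores([], [])


class TestOneToOneSets:
    def _calls(self, seed, targets):
        return [
            OrthologyCall(seed, Gene(t, sp), "ortholog", typ)
            for t, sp, typ in targets
        ]

    def test_complete_row_emitted(self):
        seed = Gene("H1", "HUMAN")
        calls = self._calls(
            seed,
            [("M1", "MOUSE", "one-to-one"), ("Y1", "YEAST", "one-to-one")],
        )
        df = one_to_one_sets({seed: calls}, ["MOUSE", "YEAST"])
        assert list(df.index) == ["H1"]
        assert df.loc["H1", "MOUSE"] == "M1"
        assert df.loc["H1", "YEAST"] == "Y1"

    def test_one_to_many_excludes_row(self):
        seed = Gene("H1", "HUMAN")
        calls = self._calls(
            seed,
            [
                ("M1", "MOUSE", "one-to-many"),
                ("M2", "MOUSE", "one-to-many"),
                ("Y1", "YEAST", "one-to-one"),
            ],
        )
        df = one_to_one_sets({seed: calls}, ["MOUSE", "YEAST"])
        assert df.empty

    def test_empty_species_list_rejected(self):
        with pytest.raises(ValueError):
            one_to_one_sets({}, [])


class TestOrthoXML:
    def test_one_to_one_group_has_two_generefs(self):
        tree = _labeled("((H1_HUMAN,M1_MOUSE),C_YEAST);")
        calls = [
            c
            for c in infer_orthology(tree, seed_leaf="H1_HUMAN")
            if c.relation == "ortholog" and c.gene_b.species == "MOUSE"
        ]
        xml = write_orthoxml(calls)
        assert xml.count("<geneRef") == 2
        assert xml.count("<orthologGroup") == 1
        assert parse_orthoxml(xml) == {calls[0].pair_key()}

    def test_many_to_many_single_group_with_paralog_nesting(self):
        tree = _labeled("((H1_HUMAN,H2_HUMAN),(M1_MOUSE,M2_MOUSE));")
        calls = infer_orthology(tree, all_vs_all=True)
        xml = write_orthoxml(calls)
        assert xml.count("<orthologGroup") == 1
        assert xml.count("<paralogGroup") == 2
        assert xml.count("<geneRef") == 4
        assert parse_orthoxml(xml) == _pairs(calls)

    def test_round_trip_on_simulated_trees(self):
        rng = np.random.default_rng(29)
        for _ in range(15):
            sp = simulate.simulate_species_tree(6, int(rng.integers(2**31)))
            rec = simulate.simulate_gene_family(
                sp, 0.8, 0.0, int(rng.integers(2**31)), min_leaves=3
            )
            tree = label_events(rec.gene_tree)
            calls = infer_orthology(tree, all_vs_all=True)
            if not any(c.relation == "ortholog" for c in calls):
                continue
            assert parse_orthoxml(write_orthoxml(calls)) == _pairs(calls)

    def test_empty_call_list_rejected(self):
        with pytest.raises(ValueError):
            write_orthoxml([])

    def test_unknown_species_rejected(self):
        call = OrthologyCall(
            Gene("A", "HUMAN"), Gene("B", "MOUSE"), "ortholog", "one-to-one"
        )
        with pytest.raises(ValueError, match="MOUSE"):
            write_orthoxml([call], known_species={"HUMAN"})


class TestTsv:
    def test_tsv_is_deterministic_and_parseable(self):
        tree = _labeled("((H1_HUMAN,M1_MOUSE),C_YEAST);")
        calls = infer_orthology(tree, seed_leaf="H1_HUMAN")
        buf = io.StringIO()
        write_tsv(calls, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0].startswith("seed_id\ttarget_id")
        assert len(lines) == 1 + len(calls)
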