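"""Generators: determinism, constructed truth, and the mscL fixture."""

import random

import pytest

from magscreen import dollo_oracle, loss_gain_ratio, min_loss_events
from magscreen.synthetic import (
    SCENARIOS,
    build_actinobacteria_fixture,
    simulate_annotated_gene_tree,
    simulate_gene_history,
    simulate_protein_families,
    simulate_species_tree,
)


class TestSpeciesTree:
    def test_two_tips_is_a_cherry(self):
        tree = simulate_species_tree(2, seed=0)
        assert len(tree.tip_ids()) == 2
        assert len(tree.root.children) == 2

    def test_same_seed_same_newick(self):
        a = simulate_species_tree(20, seed=5).to_newick()
        b = simulate_species_tree(20, seed=5).to_newick()
        assert a == b

    def test_different_seeds_differ(self):
        assert simulate_species_tree(20, seed=5).to_newick() != \
            simulate_species_tree(20, seed=6).to_newick()

    def test_binary_node_count(self):
        tree = simulate_species_tree(186, seed=1)
        tips = tree.tip_ids()
        internal = [n for n in tree.preorder() if not n.is_leaf]
        assert len(tips) == 186
        assert len(internal) == 185

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, seed=0)


class TestGeneHistory:
    def test_gain_at_root_no_losses(self):
        tree = simulate_species_tree(10, seed=2)
        child = tree.root.children[0]
        profile, truth = simulate_gene_history(tree, tree.root.id, 0, seed=1)
        assert profile.possessors == frozenset(tree.tip_ids())
        assert truth.loss_branches == frozenset()

    def test_losses_recovered_by_statistic(self):
        tree = simulate_species_tree(10, seed=3)
        profile, truth = simulate_gene_history(tree, tree.root.id, 3, seed=7)
        assert len(truth.loss_branches) == 3
        assert min_loss_events(tree, profile) == 3
        assert dollo_oracle(tree, profile) == 3

    def test_gain_on_cherry_stem_with_one_loss(self):
        # losing one tip of a 2-tip gain clade is invisible to an
        # LCA-anchored count, so this history needs the relaxed mode
        tree = simulate_species_tree(8, seed=4)
        cherry = next(
            n for n in tree.preorder()
            if not n.is_leaf and all(c.is_leaf for c in n.children)
            and len(n.children) == 2
        )
        profile, truth = simulate_gene_history(
            tree, cherry.id, 1, seed=5, allow_nested_losses=True
        )
        assert len(profile.possessors) == 1
        with pytest.raises(ValueError, match="maximum feasible"):
            simulate_gene_history(tree, cherry.id, 1, seed=5)

    def test_infeasible_losses_suggest_maximum(self):
        tree = simulate_species_tree(4, seed=0)
        with pytest.raises(ValueError, match="maximum feasible"):
            simulate_gene_history(tree, tree.root.id, 6, seed=0)

    def test_deterministic_per_seed(self):
        tree = simulate_species_tree(15, seed=9)
        p1, t1 = simulate_gene_history(tree, tree.root.id, 2, seed=11)
        p2, t2 = simulate_gene_history(tree, tree.root.id, 2, seed=11)
        assert p1.possessors == p2.possessors
        assert t1.loss_branches == t2.loss_branches

    def test_recovery_property_over_many_draws(self):
        rng = random.Random(21)
        for i in range(60):
            tree = simulate_species_tree(rng.randint(6, 25), seed=500 + i)
            internal = [n for n in tree.preorder() if not n.is_leaf]
            gain = rng.choice(internal)
            n_losses = rng.randint(0, 2)
            try:
                profile, truth = simulate_gene_history(
                    tree, gain.id, n_losses, seed=i
                )
            except ValueError:
                continue  # infeasible placement for this draw
            assert min_loss_events(tree, profile) == len(truth.loss_branches)
            assert len(profile.possessors) == len(profile.possessors)


class TestFixture:
    def test_tip_count_and_absence_pattern(self, mscl_fixture):
        tree, profile, taxa = mscl_fixture
        assert len(tree.tip_ids()) == 186
        assert len(profile.possessors) == 170
        absent = set(profile.universe) - profile.possessors
        assert len(absent) == 16
        by_genus = {}
        for t in absent:
            by_genus.setdefault(taxa[t].genus, set()).add(t)
        assert {g: len(v) for g, v in by_genus.items()} == {
            "Salinispora": 2, "Mobiluncus": 8, "Streptomyces": 2,
            "Nocardiopsis": 1, "Rubrobacter": 1, "Collinsella": 2,
        }

    def test_genera_are_monophyletic(self, mscl_fixture):
        tree, _, taxa = mscl_fixture
        by_genus = {}
        for tid in tree.tip_ids():
            by_genus.setdefault(taxa[tid].genus, []).append(tid)
        for genus, tips in by_genus.items():
            clade = {t.id for t in tree.subtree_tips(tree.mrca(tips))}
            assert clade == set(tips), f"{genus} not monophyletic"

    def test_absent_streptomyces_are_separated(self, mscl_fixture):
        tree, profile, _ = mscl_fixture
        pair = ["Streptomyces_viridochromogenes", "Streptomyces_clavuligerus"]
        between = {t.id for t in tree.subtree_tips(tree.mrca(pair))}
        assert between & profile.possessors, (
            "the two absent Streptomyces must be separated by possessors"
        )

    def test_coriobacteridae_possessor_exists(self, mscl_fixture):
        tree, profile, taxa = mscl_fixture
        corio_possessors = [
            t for t in profile.possessors
            if taxa[t].taxon_group == "Coriobacteridae"
            and taxa[t].genus != "Collinsella"
        ]
        assert corio_possessors

    def test_deterministic(self):
        a = build_actinobacteria_fixture()[0].to_newick()
        b = build_actinobacteria_fixture()[0].to_newick()
        assert a == b

    @pytest.mark.parametrize("collinsella_in_lca", [True, False])
    def test_ratio_robust_to_collinsella_placement(self, collinsella_in_lca):
        tree, profile, _ = build_actinobacteria_fixture(collinsella_in_lca)
        res = loss_gain_ratio(tree, profile)
        assert round(res.ratio, 2) == 0.04


class TestProteinFamilies:
    def test_zero_rate_keeps_root_sequence(self):
        tree = simulate_species_tree(5, seed=1)
        prot, _ = simulate_protein_families(tree, 3, root_length=40, rate=0.0, seed=2)
        for fam in ("fam000", "fam001", "fam002"):
            seqs = {
                r.sequence
                for recs in prot.values()
                for r in recs
                if r.id.split("|")[1] == fam
            }
            assert len(seqs) == 1

    def test_no_paralogs_means_one_copy_per_tip(self):
        tree = simulate_species_tree(6, seed=2)
        prot, _ = simulate_protein_families(
            tree, 4, root_length=30, rate=0.05, paralog_prob=0.0, seed=3
        )
        for taxon, recs in prot.items():
            assert len(recs) == 4

    def test_paralogs_recorded_in_truth(self):
        tree = simulate_species_tree(6, seed=2)
        prot, truths = simulate_protein_families(
            tree, 2, root_length=30, rate=0.02, paralog_prob=0.9, seed=4
        )
        assert any(t.paralog_events for t in truths)
        n_copies = sum(len(r) for r in prot.values())
        assert n_copies > 2 * 6

    def test_negative_rate_rejected(self):
        tree = simulate_species_tree(4, seed=0)
        with pytest.raises(ValueError):
            simulate_protein_families(tree, 1, rate=-0.1, seed=0)

    def test_deterministic_per_seed(self):
        tree = simulate_species_tree(5, seed=3)
        a, _ = simulate_protein_families(tree, 2, root_length=25, rate=0.1, seed=8)
        b, _ = simulate_protein_families(tree, 2, root_length=25, rate=0.1, seed=8)
        assert {t: [r.sequence for r in rs] for t, rs in a.items()} == \
            {t: [r.sequence for r in rs] for t, rs in b.items()}


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            simulate_annotated_gene_tree("martian_clade", seed=0)

    @pytest.mark.parametrize("scenario", SCENARIOS)
    def test_fixture_is_deterministic(self, scenario):
        a = simulate_annotated_gene_tree(scenario, seed=5)
        b = simulate_annotated_gene_tree(scenario, seed=5)
        assert a.tree.to_newick() == b.tree.to_newick()
        assert a.expected == b.expected
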