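"""Hit filtering, midpoint rooting, the clading rules, and operon logic."""

import itertools
import random

import pytest

from magscreen import (
    CladeSummary,
    Habitat,
    HomologHit,
    MagDecision,
    MagStatus,
    OperonGroup,
    Rule,
    ScreenConfig,
    Taxon,
    TaxonTable,
    filter_homolog_hits,
    midpoint_root,
    operon_screen,
    parse_newick,
    phylogenetic_screen,
)
from magscreen.synthetic import SCENARIOS, simulate_annotated_gene_tree
from magscreen.treemodel import Node, RootedTree, TreeValidationError


class TestFilterHomologHits:
    def hit(self, i, score=100.0, evalue=1e-10, frac=0.9):
        return HomologHit(f"h{i:03d}", score, evalue, frac)

    def test_top_hits_cap(self):
        hits = [self.hit(i, score=200 - i) for i in range(150)]
        assert len(filter_homolog_hits(hits)) == 100

    def test_low_length_fraction_removed(self):
        kept = filter_homolog_hits([self.hit(0), self.hit(1, frac=0.4)])
        assert [h.id for h in kept] == ["h000"]

    def test_weak_evalue_removed(self):
        kept = filter_homolog_hits([self.hit(0), self.hit(1, evalue=1e-3)])
        assert [h.id for h in kept] == ["h000"]

    def test_empty_input(self):
        assert filter_homolog_hits([]) == []

    def test_cap_applies_before_filters(self):
        # 100 strong-but-short hits outrank 50 weak passers: cap first
        strong_short = [self.hit(i, score=500, frac=0.1) for i in range(100)]
        weak_pass = [self.hit(100 + i, score=10) for i in range(50)]
        assert filter_homolog_hits(strong_short + weak_pass) == []


def tip_depths(tree):
    out = {}
    for tip in tree.tips():
        d, n = 0.0, tip
        while n.parent is not None:
            d += n.length or 0.0
            n = n.parent
        out[tip.id] = d
    return out


def pairwise_tip_distances(tree):
    depths = tip_depths(tree)
    dist = {}
    for a, b in itertools.combinations(tree.tip_ids(), 2):
        lca = tree.mrca([a, b])
        d_lca, n = 0.0, lca
        while n.parent is not None:
            d_lca += n.length or 0.0
            n = n.parent
        dist[(a, b)] = depths[a] + depths[b] - 2 * d_lca
    return dist


class TestMidpointRoot:
    def test_symmetric_cherry_roots_at_branch_midpoint(self):
        tree = midpoint_root(parse_newick("(A:2,B:2);"))
        depths = tip_depths(tree)
        assert depths["A"] == pytest.approx(depths["B"])

    def test_long_terminal_branch_catches_the_root(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:10):1);")
        longest = max(pairwise_tip_distances(tree).items(), key=lambda kv: kv[1])
        rooted = midpoint_root(tree)
        depths = tip_depths(rooted)
        # midpoint: deepest tip sits at half the longest tip-to-tip path
        assert max(depths.values()) == pytest.approx(longest[1] / 2)
        assert max(depths, key=depths.get) == "D"

    def test_idempotent_on_midpoint_rooted_tree(self):
        once = midpoint_root(parse_newick("((A:1,B:1):1,(C:1,D:10):1);"))
        twice = midpoint_root(once)
        d1, d2 = tip_depths(once), tip_depths(twice)
        assert d1 == pytest.approx(d2)

    def test_missing_lengths_rejected(self):
        with pytest.raises(TreeValidationError, match="branch lengths"):
            midpoint_root(parse_newick("((A,B),C);"))


def add_micromonospora(fix):
    """Graft two Micromonospora tips onto a scenario fixture's root."""
    root = fix.tree.root
    for i in (1, 2):
        root.add_child(Node(f"Micromonospora_added{i}", length=1.0))
    tree = RootedTree(root)
    extra = [
        Taxon(f"Micromonospora_added{i}", f"Micromonospora added{i}",
              "Micromonospora", "Actinobacteria", Habitat.NONMARINE)
        for i in (1, 2)
    ]
    taxa = TaxonTable(list(fix.taxa.values()) + extra)
    return tree, taxa


class TestPhylogeneticScreen:
    @pytest.mark.parametrize("scenario", SCENARIOS)
    @pytest.mark.parametrize("seed", [0, 17, 99])
    def test_scenarios_recover_expected_decisions(self, scenario, seed):
        fix = simulate_annotated_gene_tree(scenario, seed)
        d = phylogenetic_screen(fix.tree, fix.query_tips, fix.taxa)
        assert d.status == fix.expected.status
        assert d.rule == fix.expected.rule

    @pytest.mark.parametrize(
        "scenario", ["hyperosmotic_clade", "mixed_clade_majority"]
    )
    def test_micromonospora_exception_dominates(self, scenario):
        fix = simulate_annotated_gene_tree(scenario, seed=1)
        assert phylogenetic_screen(
            fix.tree, fix.query_tips, fix.taxa
        ).status is MagStatus.FINAL_MAG
        tree, taxa = add_micromonospora(fix)
        d = phylogenetic_screen(tree, fix.query_tips, taxa)
        assert d.status is MagStatus.REJECTED
        assert d.rule is Rule.MICROMONOSPORA_VERTICAL

    def test_too_many_actinobacteria_rejected(self):
        fix = simulate_annotated_gene_tree("hyperosmotic_clade", seed=2)
        cfg = ScreenConfig(actino_clade_max=1)  # queries alone exceed it
        d = phylogenetic_screen(fix.tree, fix.query_tips, fix.taxa, cfg)
        assert d.status is MagStatus.REJECTED
        assert d.rule is Rule.TOO_MANY_ACTINOBACTERIA

    def test_decision_invariant_to_child_order(self):
        for scenario in SCENARIOS:
            fix = simulate_annotated_gene_tree(scenario, seed=5)
            d1 = phylogenetic_screen(fix.tree, fix.query_tips, fix.taxa)
            for node in fix.tree.preorder():
                node.children.reverse()
            flipped = RootedTree(fix.tree.root)
            d2 = phylogenetic_screen(flipped, fix.query_tips, fix.taxa)
            assert (d1.status, d1.rule) == (d2.status, d2.rule)

    def test_missing_query_tips_raise(self):
        fix = simulate_annotated_gene_tree("hyperosmotic_clade", seed=0)
        with pytest.raises(TreeValidationError, match="query tips"):
            phylogenetic_screen(fix.tree, ["not_a_tip"], fix.taxa)

    def test_clade_summary_counts(self):
        fix = simulate_annotated_gene_tree("hyperosmotic_clade", seed=0)
        d = phylogenetic_screen(fix.tree, fix.query_tips, fix.taxa)
        assert d.clade_summary.n_hyperosmotic == 2
        assert d.clade_summary.n_other == 0
        assert d.clade_summary.n_actino_species == 2


def decision(gene, status, rule=Rule.HYPEROSMOTIC_CLADE):
    return MagDecision(gene, status, rule)


class TestOperonScreen:
    def group(self, lengths):
        return OperonGroup("op1", tuple(lengths), dict(lengths.items()))

    def test_all_final_members_stay_final(self):
        g = self.group({f"m{i}": 300 for i in range(7)})
        decisions = {m: decision(m, MagStatus.FINAL_MAG) for m in g.member_ids}
        out = operon_screen(g, decisions)
        assert all(d.status is MagStatus.FINAL_MAG for d in out.values())

    def test_short_members_inherit_longest_decision(self):
        g = self.group({"mrpD": 500, "mrpC": 60, "mrpE": 70})
        decisions = {"mrpD": decision("mrpD", MagStatus.FINAL_MAG)}
        out = operon_screen(g, decisions, min_robust_length=100)
        assert out["mrpC"].status is MagStatus.FINAL_MAG
        assert out["mrpC"].rule is Rule.OPERON_INHERITED
        assert out["mrpE"].rule is Rule.OPERON_INHERITED
        assert out["mrpD"].rule is Rule.HYPEROSMOTIC_CLADE

    def test_one_rejected_member_rejects_the_operon(self):
        g = self.group({"a": 300, "b": 300, "c": 50})
        decisions = {
            "a": decision("a", MagStatus.FINAL_MAG),
            "b": decision("b", MagStatus.REJECTED, Rule.NONHYPEROSMOTIC),
        }
        out = operon_screen(g, decisions)
        assert all(d.status is MagStatus.REJECTED for d in out.values())
        assert out["b"].rule is Rule.NONHYPEROSMOTIC

    def test_undecidable_operon_raises(self):
        g = self.group({"a": 50, "b": 60})
        with pytest.raises(ValueError, match="undecidable"):
            operon_screen(g, {})

    def test_long_member_without_decision_raises(self):
        g = self.group({"a": 300, "b": 300})
        with pytest.raises(ValueError, match="no decision"):
            operon_screen(g, {"a": decision("a", MagStatus.FINAL_MAG)})

    def test_final_status_requires_accepting_rule(self):
        with pytest.raises(ValueError):
            MagDecision("g", MagStatus.FINAL_MAG, Rule.NONHYPEROSMOTIC)
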