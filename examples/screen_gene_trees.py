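"""Phylogenetic screening of candidate genes on annotated gene trees.

Generates one gene tree per screening scenario, applies the clading
rules, and shows operon-level aggregation for short members.
"""

from magscreen import MagStatus, OperonGroup, operon_screen, phylogenetic_screen
from magscreen.synthetic import SCENARIOS, simulate_annotated_gene_tree

for scenario in SCENARIOS:
    fix = simulate_annotated_gene_tree(scenario, seed=1)
    d = phylogenetic_screen(fix.tree, fix.query_tips, fix.taxa, gene_id=scenario)
    s = d.clade_summary
    print(f"{scenario:24s} -> {d.status.value:9s} ({d.rule.value}; "
          f"clade: {s.n_hyperosmotic} hyperosmotic / {s.n_other} other, "
          f"{s.n_actino_species} Actinobacterial species)")

# operon aggregation: short members inherit the longest member's decision
fix = simulate_annotated_gene_tree("hyperosmotic_clade", seed=1)
anchor = phylogenetic_screen(fix.tree, fix.query_tips, fix.taxa, gene_id="mrpD")
group = OperonGroup("mrp", ("mrpD", "mrpC", "mrpE"),
                    {"mrpD": 520, "mrpC": 60, "mrpE": 75})
for gene, d in operon_screen(group, {"mrpD": anchor}).items():
    print(f"operon member {gene}: {d.status.value} ({d.rule.value})")

# A gene passes when its nearest clade is hyperosmotic (or every other
# major clade has a hyperosmotic majority) and is not dominated by
# Actinobacteria; two or more Micromonospora sequences anywhere in the
# tree signal vertical inheritance and reject the gene outright.
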