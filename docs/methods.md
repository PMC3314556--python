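# Methods

## The gain/loss parsimony statistic

For a gene with possessor set *P* over the tips of a rooted species tree,
the screen contrasts two extreme evolutionary histories:

* **Vertical inheritance.** The gene arose once, at the LCA of *P*, and
  was subsequently lost. The minimum number of losses *L* is the number
  of maximal subtrees strictly inside the LCA clade whose tips all lack
  the gene. This equals the Dollo small-parsimony loss count with the
  origin pinned at the LCA: once lost, a lineage never regains the gene,
  so the cheapest history deletes the gene exactly on the stem of each
  maximal absent clade.
* **Independent acquisition.** Every possessing terminal lineage gained
  the gene on its own: *G* = |*P*| events.

The ratio *L*/*G* above one supports acquisition (loss would be the more
expensive explanation), below one supports loss. Two deliberate edge
cases: *L* = 0 (the possessors form a clean clade) yields the verdict
`assumed_acquired` — a ratio of 0 would misleadingly read as
loss-supported when the pattern actually carries no loss signal — and
*L*/*G* = 1 is `indeterminate` rather than silently assigned to a side.

Counting is root-relative ("deepest branches") and therefore requires a
rooted tree. Polytomies are first-class: each child of a multifurcating
node is assessed independently as a candidate maximal absent subtree, with
no resolution attempted. Absences **outside** the LCA clade are never
counted — the calculation starts at the LCA of the possessors. A
consequence worth spelling out: a gene present in a single strain has the
strain itself as LCA, so *L* = 0 and the verdict is `assumed_acquired`,
even if a sister strain lacks it.

Two independent oracles guard the implementation: a bottom-up dynamic
programme over presence/absence states with regain forbidden
(`dollo_oracle`), and exhaustive enumeration of all internal-state
assignments for small trees (`dollo_enumeration`). The test suite checks
three-way agreement on thousands of random (tree, profile) instances.

Ratios are reported unrounded and rendered at two significant figures.

## The 186-tip Actinobacterial fixture

`build_actinobacteria_fixture` encodes the published *mscL* absence
pattern on a deterministic species tree: 186 tips, all genera
monophyletic, Coriobacteridae as the root outgroup, and *mscL* absent in
exactly 16 strains — 2 *Salinispora*, 8 *Mobiluncus* (one monophyletic
block, hence one loss event), *S. viridochromogenes* and
*S. clavuligerus* separated from each other by *mscL*-possessing
*Streptomyces* (two events), *N. dassonvillei*, *R. xylanophilus*, and 2
*Collinsella*. Genus sizes beyond the enumerated strains are arbitrary
but fixed; they cannot affect the statistic because losses are counted
per maximal absent clade and gains per possessing tip. Two variants probe
the one structural unknown: with a non-*Collinsella* Coriobacteridae
possessor the LCA of possessors is the root and *L* = 7 (7/170 = 0.041);
with the outgroup reduced to the two absent *Collinsella* their loss
falls outside the LCA clade and *L* = 6 (6/170 = 0.035). Both round to
the reported 0.04, demonstrating the value is robust to that unknown.

## Synthetic gene histories

`simulate_gene_history` plants a gene on a chosen branch and deletes it
on `n_losses` branches below, drawn by seeded rejection sampling under
three constraints (the *maximal-subtree guarantee*): loss branches are
pairwise non-nested; every loss clade keeps a possessing lineage under
its parent; and every loss branch lies inside the surviving possessors'
LCA clade. Under these constraints each loss is a maximal absent subtree
visible to the LCA-anchored count, so parsimony recovers the planted
history exactly — this backs the recovery tests. The third constraint is
necessary, not decorative: losing one child of a two-tip gain clade
leaves a single possessor whose LCA is the tip itself, making the loss
invisible. Such unrecoverable histories are still constructible with
`allow_nested_losses=True`, which lifts all three constraints and is
meant for oracle-equivalence testing only (the recorded loss set is then
an upper bound, and losses may fall outside the LCA).

## Protein-family simulation and RSD

Families evolve along the tree by per-site substitution with probability
1 − exp(−rate·branch length), uniform replacement among the 19 other
residues, no indels; duplications occur with a per-branch probability and
copies carry hierarchical labels so that true orthology (divergence at a
speciation) is exactly label equality. This is deliberately not a
realistic sequence model (no rate heterogeneity, no indels, no selection)
— its job is controlled divergence for testing the orthology stage, so a
pass demonstrates correct thresholding and reciprocal-best logic, not
robustness to alignment ambiguity in real proteomes.

RSD replaces the original BLAST-plus-ML-distance pipeline with exhaustive
all-vs-all global alignment (BLOSUM62, gap open −11 / extend −1) — at
desk scale there is no need for a heuristic prefilter. Divergence is the
fraction of non-identical columns over the **entire** alignment, gaps
counted as mismatches (the most literal reading of the published
coverage convention; an optional Kimura-style correction flag exists but
is off by default, since raw divergence is monotone for the thresholding
role it plays). The e-value analog is the Karlin–Altschul expectation
K·m·n·exp(−λS) with gapped BLOSUM62 constants (λ = 0.267, K = 0.041) and
the pair's length product as search space. A pair is orthologous iff each
is the other's smallest-divergence hit passing e-value < 1e-5 and
divergence ≤ 0.50, after removing records shorter than 350 aa (configurable;
simulations use shorter families and set `min_length` accordingly) or
flagged as mobile-element/secondary-metabolite genes. Exclusion flags are
input metadata, not computed. Ties break on divergence, then score, then
id, so calls are deterministic.

The loss screen takes the panel as the set of **non-target** genomes and
requires presence in ≥ `min_panel_presence` (default 24) of them; the
published census counted the two targets inside its 27-genome panel, but
separating the roles keeps the two screens symmetric and makes the
overlap error explicit.

## Gene-tree screening rules

Decisions are taken in a fixed order so every input yields exactly one
outcome: (0) ≥ 2 *Micromonospora* sequences anywhere in the tree →
rejected (vertical inheritance within the family); (1) the nearest clade
(smallest clade containing all query tips plus at least one other) passes
if all its non-query tips are hyperosmotic (marine + sludge/host pooled)
and it contains ≤ 25 Actinobacterial species; (2) otherwise the gene
passes if each other major clade — children of the root not containing
the query — has a strict hyperosmotic majority among habitat-annotated
tips; (3) a hyperosmotic clade that exceeds the Actinobacteria cap is
rejected as such; (4) everything else is rejected as non-hyperosmotic.

Genuinely open readings are behind config switches with documented
defaults: the ≤ 25-species cap is counted within the decisive clade
(`actino_count_scope="clade"`; tree-wide counting would reject nearly any
tree of Actinobacterial homologs), species are counted by distinct taxon
name rather than tip count, the majority rule is evaluated per clade
(`majority_mode="per_clade"`; pooled available), and unknown-habitat tips
are excluded from majority denominators but fail the "entirely
hyperosmotic" test. Midpoint rooting of gene trees is implemented
directly (longest tip-to-tip path, lexicographic tie-break on the tip
pair, edge split, unifurcation suppression) because the delegated rooting
routine corrupted two-tip trees and trees whose midpoint coincides with
the current root.

Operon aggregation is conservative: members shorter than
`min_robust_length` (default 100 aa — the source material says only "too
short", so the value is explicit and configurable) inherit the decision
of the longest decided member; a single rejected decided member rejects
the whole operon.

## Candidate selection and reporting

The four functional classes (electron transport/complex I, sodium
transport, ABC transport, channels and pores) are matched by
case-insensitive substring sets. The published keyword lists live in
supplementary material that is not reproduced here, so the defaults are a
documented stand-in with standard product vocabulary, replaceable via
JSON. A gene matching several classes goes to the first match in class
order and the collision is logged.

The summary table reports candidate and final counts per class, their
subtotals, comparative-genomics gains and losses, the overlap between
the functional and gain routes, and a grand total defined as
`final subtotal + gains + losses − overlap`. The printed grand totals in
the source material are not derivable from its printed components; the
implementation reports the invariant-consistent combination and exposes
every component rather than forcing agreement.

## Problem sizes and determinism

All generators take explicit seeds and never touch global random state.
The test suite exercises the statistic against its oracles on 1,000
random instances (trees up to 50 tips) plus exhaustive enumeration up to
12 tips, recovers ≥ 200 simulated histories, and runs the orthology
recovery at 30 genomes × 50 families of 120-aa proteins — sizes chosen so
the full suite completes in a couple of minutes while still covering
every rule path. The acceptance script reports only deterministic
quantities; its `--seed` is accepted for interface uniformity.

## Known limitations

* Sequence simulation has no indels, rate heterogeneity, or realistic
  substitution matrix; alignment-quality failure modes of RSD are out of
  scope.
* Habitat and exclusion annotations are inputs; nothing is inferred from
  sequence.
* The screen does not build gene trees (alignment + ML inference are
  upstream of this package) and does not perform probabilistic
  ancestral-state reconstruction — the statistic is parsimony-based by
  design.
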