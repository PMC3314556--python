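"""Phylogenetic screening of candidate genes on annotated gene trees.

A candidate gene passes when its gene tree shows recent shared ancestry
with bacteria from hyperosmotic environments (marine, sludge,
host-associated). The decision procedure, in fixed order:

0. any tree containing two or more *Micromonospora* sequences is rejected
   outright (vertical inheritance within the family);
1. the *nearest clade* — the smallest clade holding all query sequences
   plus at least one other sequence — passes if every non-query tip is
   hyperosmotic and the clade holds at most ``actino_clade_max``
   Actinobacterial species;
2. otherwise the gene still passes if, in every other major clade
   (children of the root not containing the query), a strict majority of
   habitat-annotated tips is hyperosmotic;
3. a clade that is hyperosmotic but too Actinobacteria-rich is rejected
   as ``too_many_actinobacteria``; anything else as ``nonhyperosmotic``.

Operon members too short for a robust phylogeny inherit the decision of
the longest decided member; a single rejected member rejects the operon.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .orthologs import ScreenConfig
from .treemodel import Habitat, RootedTree, TaxonTable, TreeValidationError

__all__ = [
    "MagStatus",
    "Rule",
    "CladeSummary",
    "MagDecision",
    "HomologHit",
    "OperonGroup",
    "filter_homolog_hits",
    "midpoint_root",
    "phylogenetic_screen",
    "operon_screen",
]


class MagStatus(str, enum.Enum):
    CANDIDATE = "candidate"
    FINAL_MAG = "final_mag"
    REJECTED = "rejected"


class Rule(str, enum.Enum):
    HYPEROSMOTIC_CLADE = "hyperosmotic_clade"
    MAJORITY_OTHER_CLADES = "majority_other_clades"
    TOO_MANY_ACTINOBACTERIA = "too_many_actinobacteria"
    MICROMONOSPORA_VERTICAL = "micromonospora_vertical"
    NONHYPEROSMOTIC = "nonhyperosmotic"
    OPERON_INHERITED = "operon_inherited"


_FINAL_RULES = {
    Rule.HYPEROSMOTIC_CLADE,
    Rule.MAJORITY_OTHER_CLADES,
    Rule.OPERON_INHERITED,
}


@dataclass(frozen=True)
class CladeSummary:
    n_hyperosmotic: int = 0
    n_other: int = 0
    n_actino_species: int = 0


@dataclass(frozen=True)
class MagDecision:
    gene_id: str
    status: MagStatus
    rule: Rule
    clade_summary: CladeSummary = field(default_factory=CladeSummary)

    def __post_init__(self) -> None:
        if self.status is MagStatus.FINAL_MAG and self.rule not in _FINAL_RULES:
            raise ValueError(
                f"final_mag incompatible with rule {self.rule.value!r}"
            )


@dataclass(frozen=True)
class HomologHit:
    """One scored homolog from a database search."""

    id: str
    score: float
    evalue_analog: float
    len_frac: float  # hit length / query length


def filter_homolog_hits(
    hits: Sequence[HomologHit], cfg: Optional[ScreenConfig] = None
) -> list[HomologHit]:
    """Keep the top hits by score, then apply e-value and length filters."""
    cfg = cfg or ScreenConfig()
    top = sorted(hits, key=lambda h: (-h.score, h.id))[: cfg.top_hits]
    return [
        h
        for h in top
        if h.evalue_analog < cfg.blast_evalue_max
        and h.len_frac >= cfg.min_hit_len_frac
    ]


def _flip(node, exclude):
    """Rebuild ``node`` as a subtree hanging away from ``exclude``: its old
    parent chain becomes a child. The returned node's length is unset."""
    from .treemodel import Node

    kids = []
    for c in node.children:
        if c is exclude:
            continue
        kids.append((c, c.length))
    if node.parent is not None:
        kids.append((_flip(node.parent, exclude=node), node.length))
    new = Node(node.id if node.is_leaf else "", support=node.support)
    for k, length in kids:
        k.length = length
        new.add_child(k)
    return new


def _suppress_unifurcations(node):
    for child in list(node.children):
        _suppress_unifurcations(child)
    if len(node.children) == 1 and node.parent is not None:
        only = node.children[0]
        only.length = (only.length or 0.0) + (node.length or 0.0)
        siblings = node.parent.children
        siblings[siblings.index(node)] = only
        only.parent = node.parent


def midpoint_root(tree: RootedTree) -> RootedTree:
    """Re-root at the midpoint of the longest tip-to-tip path.

    The input rooting is ignored (the tree is treated as unrooted); every
    branch must carry a length. Ties on the longest path break on the
    lexicographically smallest tip pair, so rooting is deterministic.
    """
    from .treemodel import Node

    tree = tree.copy()
    for node in tree.preorder():
        if node.parent is not None and node.length is None:
            raise TreeValidationError(
                "midpoint rooting requires branch lengths on every branch"
            )

    depths: dict[str, float] = {}
    for tip in tree.tips():
        d, n = 0.0, tip
        while n.parent is not None:
            d += n.length
            n = n.parent
        depths[tip.id] = d

    tips = sorted(tree.tip_ids())
    if len(tips) < 2:
        raise TreeValidationError("midpoint rooting needs at least two tips")
    best = None  # (-distance, tip_a, tip_b)
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            lca = tree.mrca([a, b])
            d_lca, n = 0.0, lca
            while n.parent is not None:
                d_lca += n.length
                n = n.parent
            dist = depths[a] + depths[b] - 2 * d_lca
            key = (-dist, a, b)
            if best is None or key < best:
                best = key
    dmax, tip_a, tip_b = -best[0], best[1], best[2]

    # path tip_a -> lca -> tip_b
    up, n = [], tree.node(tip_a)
    anc_b = set()
    m = tree.node(tip_b)
    while m is not None:
        anc_b.add(id(m))
        m = m.parent
    while id(n) not in anc_b:
        up.append(n)
        n = n.parent
    lca = n
    down, m = [], tree.node(tip_b)
    while m is not lca:
        down.append(m)
        m = m.parent
    path = up + [lca] + list(reversed(down))

    half = dmax / 2.0
    cum = 0.0
    for u, v in zip(path, path[1:]):
        child = u if u.parent is v else v
        elen = child.length
        if cum + elen >= half - 1e-12:
            x_from_u = half - cum
            x_from_child = x_from_u if child is u else elen - x_from_u
            break
        cum += elen
    else:  # pragma: no cover - dmax/2 always lies on the path
        raise AssertionError("midpoint not found on longest path")

    parent = child.parent
    rest = _flip(parent, exclude=child)
    rest.length = elen - x_from_child
    child.parent = None
    child.length = x_from_child
    root = Node("", length=0.0)
    root.add_child(child)
    root.add_child(rest)
    _suppress_unifurcations(root)
    return RootedTree(root)


def _habitat(taxa: TaxonTable, tip_id: str) -> Habitat:
    try:
        return taxa[tip_id].habitat
    except KeyError:
        raise TreeValidationError(
            f"gene-tree tip {tip_id!r} missing from taxon table"
        ) from None


def phylogenetic_screen(
    gene_tree: RootedTree,
    query_tips: Sequence[str],
    taxa: TaxonTable,
    cfg: Optional[ScreenConfig] = None,
    gene_id: str = "",
) -> MagDecision:
    """Decide whether a candidate gene shows hyperosmotic shared ancestry."""
    cfg = cfg or ScreenConfig()
    queries = set(query_tips)
    if not queries:
        raise ValueError("no query tips given")
    tree_tips = set(gene_tree.tip_ids())
    missing = queries - tree_tips
    if missing:
        raise TreeValidationError(f"query tips not in gene tree: {sorted(missing)}")
    gene_id = gene_id or next(iter(sorted(queries)))

    # rule 0: >= 2 Micromonospora sequences anywhere => vertical inheritance
    n_micromonospora = sum(
        1 for t in tree_tips if t in taxa and taxa[t].genus == "Micromonospora"
    )
    if n_micromonospora >= 2:
        return MagDecision(gene_id, MagStatus.REJECTED, Rule.MICROMONOSPORA_VERTICAL)

    # nearest clade: smallest clade containing all queries plus >=1 other tip
    node = gene_tree.mrca(sorted(queries))
    while {t.id for t in gene_tree.subtree_tips(node)} <= queries:
        if node.parent is None:
            raise TreeValidationError("gene tree contains only query tips")
        node = node.parent
    clade_tips = [t.id for t in gene_tree.subtree_tips(node)]
    non_query = [t for t in clade_tips if t not in queries]

    n_hyper = sum(1 for t in non_query if _habitat(taxa, t).is_hyperosmotic)
    n_other = len(non_query) - n_hyper
    count_scope = (
        clade_tips if cfg.actino_count_scope == "clade" else sorted(tree_tips)
    )
    actino_species = {
        taxa[t].name for t in count_scope if t in taxa and taxa[t].is_actinobacterium
    }
    summary = CladeSummary(n_hyper, n_other, len(actino_species))

    # unknown-habitat tips are not hyperosmotic, so they fail this test too
    habitat_ok = n_other == 0
    actino_ok = len(actino_species) <= cfg.actino_clade_max

    if habitat_ok and actino_ok:
        return MagDecision(gene_id, MagStatus.FINAL_MAG, Rule.HYPEROSMOTIC_CLADE, summary)

    # rule 2: strict hyperosmotic majority in (each of) the other major clades
    other_clades = [
        child
        for child in gene_tree.root.children
        if not ({t.id for t in gene_tree.subtree_tips(child)} & queries)
    ]
    if other_clades:
        def annotated(tips):
            return [t for t in tips if _habitat(taxa, t) is not Habitat.UNKNOWN]

        if cfg.majority_mode == "pooled":
            pool = annotated(
                t.id for c in other_clades for t in gene_tree.subtree_tips(c)
            )
            pools = [pool] if pool else []
        else:
            pools = []
            for c in other_clades:
                pool = annotated(t.id for t in gene_tree.subtree_tips(c))
                if not pool:
                    pools = []
                    break
                pools.append(pool)
        if pools and all(
            sum(1 for t in pool if _habitat(taxa, t).is_hyperosmotic) * 2 > len(pool)
            for pool in pools
        ):
            return MagDecision(
                gene_id, MagStatus.FINAL_MAG, Rule.MAJORITY_OTHER_CLADES, summary
            )

    if habitat_ok and not actino_ok:
        return MagDecision(
            gene_id, MagStatus.REJECTED, Rule.TOO_MANY_ACTINOBACTERIA, summary
        )
    return MagDecision(gene_id, MagStatus.REJECTED, Rule.NONHYPEROSMOTIC, summary)


@dataclass(frozen=True)
class OperonGroup:
    """An operon whose members are screened as one evolutionary unit."""

    operon_id: str
    member_ids: tuple[str, ...]
    member_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("an operon group needs at least two members")
        missing = [m for m in self.member_ids if m not in self.member_lengths]
        if missing:
            raise ValueError(f"missing lengths for operon members: {missing}")


def operon_screen(
    group: OperonGroup,
    decisions: Mapping[str, Optional[MagDecision]],
    min_robust_length: int = 100,
) -> dict[str, MagDecision]:
    """Propagate per-member decisions across an operon.

    Members shorter than ``min_robust_length`` with no decision of their
    own inherit the decision of the longest decided member (rule
    ``operon_inherited``). One rejected decided member rejects the whole
    operon; the operon is final only when every decided member is final.
    """
    decided: dict[str, MagDecision] = {}
    short: list[str] = []
    for member in group.member_ids:
        d = decisions.get(member)
        if d is not None and d.status is not MagStatus.CANDIDATE:
            decided[member] = d
        elif group.member_lengths[member] < min_robust_length:
            short.append(member)
        else:
            raise ValueError(
                f"operon member {member!r} has no decision and is not short"
            )
    if not decided:
        raise ValueError(f"operon {group.operon_id!r} undecidable: no member decided")

    any_rejected = any(d.status is MagStatus.REJECTED for d in decided.values())
    longest = max(decided, key=lambda m: (group.member_lengths[m], m))
    anchor = decided[longest]

    out: dict[str, MagDecision] = {}
    for member in group.member_ids:
        if member in decided:
            d = decided[member]
            status = MagStatus.REJECTED if any_rejected else d.status
            rule = d.rule
            if status is MagStatus.REJECTED and d.status is not MagStatus.REJECTED:
                rule = Rule.OPERON_INHERITED  # dragged down by a sibling member
            out[member] = MagDecision(member, status, rule, d.clade_summary)
        else:
            status = MagStatus.REJECTED if any_rejected else anchor.status
            out[member] = MagDecision(
                member, status, Rule.OPERON_INHERITED, anchor.clade_summary
            )
    return out
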