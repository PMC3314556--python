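"""Minimum-loss / maximum-gain parsimony statistic on a rooted species tree.

Given a gene's presence/absence pattern over the tips of a rooted species
tree, the statistic asks which of two extreme histories is cheaper:

* **vertical inheritance** — a single origin at the last common ancestor
  (LCA) of all possessing strains followed by the minimum number of loss
  events (Dollo parsimony), counted as the number of *maximal* subtrees
  within the LCA clade whose strains all lack the gene; or
* **independent acquisition** — one gain per possessing terminal lineage,
  i.e. the number of possessing tips.

The ratio (minimum losses / maximum gains) above one supports horizontal
acquisition, below one supports gene loss. A pattern with no internal
absences (ratio numerator 0) carries no loss signal and is reported as
``assumed_acquired``; a ratio of exactly one is ``indeterminate``.

Two independent oracles (:func:`dollo_oracle`, :func:`dollo_enumeration`)
verify the maximal-subtree count against dynamic-programming and
brute-force formulations of Dollo small parsimony.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import product

from .treemodel import Node, PresenceProfile, RootedTree, TreeValidationError

__all__ = [
    "Verdict",
    "GainLossResult",
    "lca_of_possessors",
    "min_loss_events",
    "max_gain_events",
    "loss_gain_ratio",
    "dollo_oracle",
    "dollo_enumeration",
    "render_ratio",
]

_INF = float("inf")


class Verdict(str, enum.Enum):
    GAIN_SUPPORTED = "gain_supported"
    LOSS_SUPPORTED = "loss_supported"
    INDETERMINATE = "indeterminate"
    ASSUMED_ACQUIRED = "assumed_acquired"


@dataclass(frozen=True)
class GainLossResult:
    gene_id: str
    lca_node: str
    n_loss_min: int
    n_gain_max: int
    ratio: float
    verdict: Verdict

    def __post_init__(self) -> None:
        assert self.n_gain_max > 0
        assert self.ratio == self.n_loss_min / self.n_gain_max


def _check_profile(tree: RootedTree, profile: PresenceProfile) -> frozenset[str]:
    if profile.universe:
        profile.validate_against_tree(tree)
    if not profile.possessors:
        raise ValueError(
            f"gene {profile.gene_id!r} absent everywhere; no LCA to start from"
        )
    tips = set(tree.tip_ids())
    unknown = profile.possessors - tips
    if unknown:
        raise TreeValidationError(
            f"possessors not in tree: {sorted(unknown)[:5]}"
        )
    return profile.possessors


def lca_of_possessors(tree: RootedTree, profile: PresenceProfile) -> str:
    """Id of the deepest node ancestral to every possessing tip."""
    possessors = _check_profile(tree, profile)
    return tree.mrca(sorted(possessors)).id


def min_loss_events(tree: RootedTree, profile: PresenceProfile) -> int:
    """Minimum loss count under a single origin at the possessors' LCA.

    Counts the maximal subtrees strictly within the LCA clade in which
    every strain lacks the gene. Each child of a polytomy is a candidate
    maximal absent subtree in its own right; absences outside the LCA
    clade are never counted.
    """
    possessors = _check_profile(tree, profile)
    lca = tree.mrca(sorted(possessors))

    count = 0
    stack = [lca]
    while stack:
        node = stack.pop()
        for child in node.children:
            if any(t.id in possessors for t in tree.subtree_tips(child)):
                stack.append(child)
            else:
                count += 1
    return count


def max_gain_events(tree: RootedTree, profile: PresenceProfile) -> int:
    """Gain count assuming each possessing terminal lineage acquired the gene."""
    return len(_check_profile(tree, profile))


def loss_gain_ratio(tree: RootedTree, profile: PresenceProfile) -> GainLossResult:
    """Assemble the full gain/loss verdict for one gene."""
    lca = lca_of_possessors(tree, profile)
    losses = min_loss_events(tree, profile)
    gains = max_gain_events(tree, profile)
    ratio = losses / gains
    if losses == 0:
        verdict = Verdict.ASSUMED_ACQUIRED
    elif ratio > 1:
        verdict = Verdict.GAIN_SUPPORTED
    elif ratio < 1:
        verdict = Verdict.LOSS_SUPPORTED
    else:
        verdict = Verdict.INDETERMINATE
    return GainLossResult(
        gene_id=profile.gene_id,
        lca_node=lca,
        n_loss_min=losses,
        n_gain_max=gains,
        ratio=ratio,
        verdict=verdict,
    )


def render_ratio(ratio: float) -> str:
    """Two-significant-figure rendering used in reports (e.g. 2.8, 0.04)."""
    return format(ratio, ".2g")


def dollo_oracle(tree: RootedTree, profile: PresenceProfile) -> int:
    """Dollo small-parsimony loss count by dynamic programming.

    Independent of :func:`min_loss_events`: fixes presence at the
    possessors' LCA and minimises the number of presence-to-absence
    transitions bottom-up, with regain forbidden (once absent, a whole
    subtree stays absent).
    """
    possessors = _check_profile(tree, profile)
    lca = tree.mrca(sorted(possessors))

    # cost[node] = (cost if present at node, cost if absent at node)
    cost: dict[int, tuple[float, float]] = {}
    order: list[Node] = []
    stack = [lca]
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(n.children)
    for node in reversed(order):
        if node.is_leaf:
            present = 0.0 if node.id in possessors else _INF
            absent = _INF if node.id in possessors else 0.0
        else:
            present = 0.0
            absent = 0.0
            for child in node.children:
                cp, ca = cost[id(child)]
                present += min(cp, 1.0 + ca)  # loss event on the child branch
                absent += ca  # no regain below an absent ancestor
        cost[id(node)] = (present, absent)

    result = cost[id(lca)][0]
    assert result < _INF
    return int(result)


def dollo_enumeration(tree: RootedTree, profile: PresenceProfile) -> int:
    """Exhaustive Dollo loss count for small trees (<= ~12 tips).

    Enumerates every presence/absence assignment to the internal nodes of
    the LCA clade, rejects assignments with an absence-to-presence edge
    (regain), and returns the minimum number of presence-to-absence edges.
    """
    possessors = _check_profile(tree, profile)
    lca = tree.mrca(sorted(possessors))

    nodes = []
    stack = [lca]
    while stack:
        n = stack.pop()
        nodes.append(n)
        stack.extend(n.children)
    internal = [n for n in nodes if not n.is_leaf]
    if len(internal) > 20:
        raise ValueError("enumeration oracle limited to small trees")

    fixed = {id(n): (n.id in possessors) for n in nodes if n.is_leaf}
    best = _INF
    for states in product((True, False), repeat=len(internal)):
        assign = dict(fixed)
        for n, s in zip(internal, states):
            assign[id(n)] = s
        if not assign[id(lca)]:  # origin fixed at the LCA
            continue
        losses = 0
        valid = True
        for n in nodes:
            for child in n.children:
                p, c = assign[id(n)], assign[id(child)]
                if not p and c:  # regain forbidden under Dollo
                    valid = False
                    break
                if p and not c:
                    losses += 1
            if not valid:
                break
        if valid and losses < best:
            best = losses
    assert best < _INF
    return int(best)
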