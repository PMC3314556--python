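"""Rooted trees, taxon metadata, and presence/absence profiles.

Shared data structures for the gain/loss statistic and the gene-tree
screening rules: a lightweight rooted tree (multifurcations allowed) with
newick I/O delegated to dendropy, a validated taxon table keyed by habitat
class, and per-gene presence profiles over a fixed taxon universe.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import dendropy
import pandas as pd

__all__ = [
    "Habitat",
    "Taxon",
    "TaxonTable",
    "Node",
    "RootedTree",
    "PresenceProfile",
    "NewickParseError",
    "TreeValidationError",
    "read_newick",
    "write_newick",
    "load_taxa",
    "load_presence",
    "write_presence",
]


class NewickParseError(ValueError):
    """Raised when a newick file cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a tree, taxon table, or profile violates an invariant."""


class Habitat(str, enum.Enum):
    """Habitat class of a strain.

    ``marine`` and ``hyperosmotic_other`` (sludge, host-associated) are
    pooled as "hyperosmotic" by the screening rules; the distinction only
    matters for provenance.
    """

    MARINE = "marine"
    HYPEROSMOTIC_OTHER = "hyperosmotic_other"
    NONMARINE = "nonmarine"
    UNKNOWN = "unknown"

    @property
    def is_hyperosmotic(self) -> bool:
        return self in (Habitat.MARINE, Habitat.HYPEROSMOTIC_OTHER)


@dataclass(frozen=True)
class Taxon:
    """One strain/genome with the annotations the screen consumes."""

    id: str
    name: str
    genus: str
    taxon_group: str
    habitat: Habitat
    is_actinobacterium: bool = True
    is_marine_origin: bool = False

    def __post_init__(self) -> None:
        if self.habitat is Habitat.MARINE and not self.is_marine_origin:
            raise TreeValidationError(
                f"taxon {self.id!r}: habitat 'marine' requires marine_origin=True"
            )


class TaxonTable(Mapping[str, Taxon]):
    """Immutable mapping of taxon id -> :class:`Taxon` with unique ids."""

    def __init__(self, taxa: Iterable[Taxon]):
        self._taxa: dict[str, Taxon] = {}
        for t in taxa:
            if t.id in self._taxa:
                raise TreeValidationError(f"duplicate taxon id {t.id!r}")
            self._taxa[t.id] = t

    def __getitem__(self, key: str) -> Taxon:
        return self._taxa[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._taxa)

    def __len__(self) -> int:
        return len(self._taxa)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "id": t.id,
                "name": t.name,
                "genus": t.genus,
                "taxon_group": t.taxon_group,
                "habitat": t.habitat.value,
                "marine_origin": int(t.is_marine_origin),
                "actinobacterium": int(t.is_actinobacterium),
            }
            for t in self._taxa.values()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class Node:
    """A node of a rooted tree; the branch above a node shares its id."""

    __slots__ = ("id", "parent", "children", "length", "support")

    def __init__(
        self,
        id: str,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.id = id
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.length = length
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def __repr__(self) -> str:  # pragma: no cover
        kind = "tip" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.id} {kind}>"


class RootedTree:
    """Rooted, possibly multifurcating tree with uniquely labelled tips.

    Tip ids double as taxon ids; internal nodes get stable generated ids
    (``_n0`` at the root, preorder). The tree is treated as rooted exactly
    as given — no implicit re-rooting happens here.
    """

    def __init__(self, root: Node):
        self.root = root
        self._index: dict[str, Node] = {}
        self._reindex()

    # -- construction / indexing -------------------------------------------

    def _reindex(self) -> None:
        self._index.clear()
        counter = 0
        for node in self.preorder():
            if not node.is_leaf or node.id is None or node.id == "":
                if node.is_leaf:
                    raise TreeValidationError("tip with empty label")
                node.id = f"_n{counter}"
                counter += 1
            if node.id in self._index:
                raise TreeValidationError(f"duplicate node id {node.id!r}")
            self._index[node.id] = node

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def tip_ids(self) -> list[str]:
        return [n.id for n in self.tips()]

    def node(self, node_id: str) -> Node:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"no node with id {node_id!r} in tree") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def __len__(self) -> int:
        return len(self._index)

    def subtree_tips(self, node: Node | str) -> list[Node]:
        if isinstance(node, str):
            node = self.node(node)
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(n.children)
        return out

    def mrca(self, tip_ids: Sequence[str]) -> Node:
        """Most recent common ancestor of the given tips (a tip for one id)."""
        if not tip_ids:
            raise ValueError("mrca of an empty tip set is undefined")
        paths = []
        for tid in tip_ids:
            node: Optional[Node] = self.node(tid)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        anc = None
        for level in zip(*paths):
            first = level[0]
            if all(n is first for n in level):
                anc = first
            else:
                break
        assert anc is not None  # all paths start at the root
        return anc

    # -- dendropy bridge ----------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "RootedTree":
        def convert(dnode: dendropy.Node) -> Node:
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else dnode.label
                if not label:
                    raise TreeValidationError("tip with empty label")
                node = Node(str(label), length=dnode.edge.length)
            else:
                support = None
                raw = dnode.label
                if raw is not None:
                    try:
                        support = float(raw)
                    except (TypeError, ValueError):
                        support = None  # non-numeric internal labels ignored
                node = Node("", length=dnode.edge.length, support=support)
                for child in dnode.child_nodes():
                    node.add_child(convert(child))
            return node

        root = convert(dtree.seed_node)
        tree = cls(root)
        labels = tree.tip_ids()
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        return tree

    def to_dendropy(self) -> dendropy.Tree:
        ns = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=ns)
        dtree.is_rooted = True

        def convert(node: Node, dnode: dendropy.Node) -> None:
            dnode.edge.length = node.length
            if node.is_leaf:
                dnode.taxon = ns.new_taxon(label=node.id)
            else:
                if node.support is not None:
                    dnode.label = format(node.support, "g")
                for child in node.children:
                    convert(child, dnode.new_child())

        convert(self.root, dtree.seed_node)
        return dtree

    def to_newick(self) -> str:
        has_lengths = any(n.length is not None for n in self.preorder())
        s = self.to_dendropy().as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_edge_lengths=not has_lengths,
            unquoted_underscores=True,
        )
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    def copy(self) -> "RootedTree":
        def clone(node: Node) -> Node:
            new = Node(node.id if node.is_leaf else "", node.length, node.support)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return RootedTree(clone(self.root))


def read_newick(path: str | Path) -> RootedTree:
    """Read a rooted tree from a newick file.

    Numeric internal-node labels are interpreted as support values;
    non-numeric ones are dropped. Duplicate tip labels raise.
    """
    path = Path(path)
    text = path.read_text()
    return parse_newick(text)


def parse_newick(text: str) -> RootedTree:
    if not text.strip():
        raise NewickParseError("empty newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Duplicate" in type(exc).__name__:
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return RootedTree.from_dendropy(dtree)


def write_newick(tree: RootedTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick())


_HABITAT_TOKENS = {h.value: h for h in Habitat}


def load_taxa(path: str | Path) -> TaxonTable:
    """Load a taxon metadata TSV.

    Required columns: ``id, name, genus, taxon_group, habitat,
    marine_origin``. An ``actinobacterium`` 0/1 column is optional
    (default 1). Unknown habitat tokens and duplicate ids raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["id", "name", "genus", "taxon_group", "habitat", "marine_origin"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TreeValidationError(f"taxon table missing columns: {missing}")
    taxa = []
    for row in df.itertuples(index=False):
        habitat_token = str(row.habitat)
        if habitat_token not in _HABITAT_TOKENS:
            raise TreeValidationError(
                f"unknown habitat {habitat_token!r} for taxon {row.id!r}; "
                f"allowed: {sorted(_HABITAT_TOKENS)}"
            )
        is_actino = True
        if "actinobacterium" in df.columns:
            is_actino = bool(int(getattr(row, "actinobacterium")))
        taxa.append(
            Taxon(
                id=str(row.id),
                name=str(row.name),
                genus=str(row.genus),
                taxon_group=str(row.taxon_group),
                habitat=_HABITAT_TOKENS[habitat_token],
                is_actinobacterium=is_actino,
                is_marine_origin=bool(int(row.marine_origin)),
            )
        )
    return TaxonTable(taxa)


@dataclass(frozen=True)
class PresenceProfile:
    """Which taxa of a fixed universe possess a gene."""

    gene_id: str
    possessors: frozenset[str]
    universe: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "possessors", frozenset(self.possessors))
        object.__setattr__(self, "universe", tuple(self.universe))
        extra = self.possessors - set(self.universe)
        if extra:
            raise TreeValidationError(
                f"profile {self.gene_id!r}: possessors outside universe: "
                f"{sorted(extra)[:5]}"
            )

    def validate_against_tree(self, tree: RootedTree) -> None:
        """Raise unless the profile's universe equals the tree's tip set."""
        tips = set(tree.tip_ids())
        if set(self.universe) != tips:
            only_profile = sorted(set(self.universe) - tips)[:5]
            only_tree = sorted(tips - set(self.universe))[:5]
            raise TreeValidationError(
                f"profile {self.gene_id!r} universe does not match tree tips "
                f"(profile-only: {only_profile}, tree-only: {only_tree})"
            )


def load_presence(path: str | Path) -> list[PresenceProfile]:
    """Read a genes x taxa 0/1 TSV (first column gene id, header taxon ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    universe = tuple(str(c) for c in df.columns)
    profiles = []
    for gene_id, row in df.iterrows():
        possessors = frozenset(t for t, v in zip(universe, row) if int(v) == 1)
        profiles.append(PresenceProfile(str(gene_id), possessors, universe))
    return profiles


def write_presence(profiles: Sequence[PresenceProfile], path: str | Path) -> None:
    if not profiles:
        raise ValueError("no profiles to write")
    universe = profiles[0].universe
    data = {
        p.gene_id: [1 if t in p.possessors else 0 for t in universe]
        for p in profiles
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(universe))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
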