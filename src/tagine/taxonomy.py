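"""Rank-based taxonomic trees built from lineage strings.

The tree is the scaffold for hierarchical feature engineering: each input
feature is a leaf, every internal node is a clade whose abundance is the sum
of its children's abundances, and "collapsing to a level" yields the frontier
of coarse features that seeds the expansion queue.

Two structural conventions matter downstream and are applied at build time:

* An artificial root is always added above the top rank, so "one level below
  the root" is well defined even for single-kingdom data; depths are counted
  from this root (root = 0).
* Single-child chains (typically produced by unassigned intermediate ranks)
  are compressed into one node whose display name concatenates the chain with
  ``|``. A chain adds parameters without changing any clade's leaf set, so an
  information-criterion comparison along it can never favour expansion; left
  uncompressed it would freeze exploration below the chain.

Unassigned rank tokens ("g__", "NA", "unclassified", "") are kept as
placeholder names scoped under their parent: two "unclassified" genera under
different families remain distinct nodes, because node identity is the full
path, not the bare token.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .table import AbundanceTable

__all__ = [
    "TaxNode",
    "TaxTree",
    "TaxonomyError",
    "build_tree",
    "aggregate",
    "collapse_to_level",
    "to_newick",
]

ROOT_ID = "<root>"


class TaxonomyError(ValueError):
    """Structural problem in the input lineages or tree/table mismatch."""


@dataclass
class TaxNode:
    node_id: str
    name: str
    rank_depth: int = 0
    parent: "TaxNode | None" = None
    children: list["TaxNode"] = field(default_factory=list)
    leaf_ids: tuple[str, ...] = ()
    # set for leaves only: the input feature this leaf represents
    feature_id: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def path(self) -> tuple[str, ...]:
        """Names from the root's first child down to this node."""
        names: list[str] = []
        node: TaxNode | None = self
        while node is not None and node.parent is not None:
            names.append(node.name)
            node = node.parent
        return tuple(reversed(names))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"{len(self.children)} children"
        return f"TaxNode({self.node_id!r}, depth={self.rank_depth}, {kind})"


@dataclass
class TaxTree:
    root: TaxNode
    nodes: dict[str, TaxNode]
    n_leaves: int

    def leaves(self) -> list[TaxNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    def internal_nodes(self) -> list[TaxNode]:
        return [n for n in self.nodes.values() if not n.is_leaf]

    def leaf_feature_ids(self) -> set[str]:
        return {n.feature_id for n in self.leaves() if n.feature_id is not None}

    def max_depth(self) -> int:
        return max(n.rank_depth for n in self.nodes.values())

    def lineages(self) -> dict[str, tuple[str, ...]]:
        """Read lineages back out; build_tree on them is structure-preserving."""
        out: dict[str, tuple[str, ...]] = {}
        for leaf in self.leaves():
            if leaf.feature_id is not None:
                out[leaf.feature_id] = leaf.path()
        return out


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

class _Trie:
    __slots__ = ("name", "children", "feature_id")

    def __init__(self, name: str):
        self.name = name
        self.children: dict[str, _Trie] = {}
        self.feature_id: str | None = None


def build_tree(lineages: Mapping[str, Sequence[str]]) -> TaxTree:
    """Build the rooted taxonomy whose leaves are exactly the input features.

    Parameters
    ----------
    lineages:
        ``feature_id -> ordered lineage tokens`` (coarsest first). Tokens are
        taken verbatim; identical prefixes must name identical ancestors.

    Raises
    ------
    TaxonomyError
        On empty input, an empty lineage, two features claiming the same full
        path, or a feature whose path is a strict prefix of another's (a leaf
        cannot sit at an internal position).
    """
    if not lineages:
        raise TaxonomyError("no lineages given")

    trie = _Trie("root")
    for fid in sorted(lineages):
        tokens = [str(t) for t in lineages[fid]]
        if not tokens:
            raise TaxonomyError(f"feature {fid!r} has an empty lineage")
        node = trie
        for tok in tokens:
            if node.feature_id is not None:
                raise TaxonomyError(
                    f"feature {node.feature_id!r} at path "
                    f"{';'.join(tokens)!r} is an ancestor of feature {fid!r}"
                )
            node = node.children.setdefault(tok, _Trie(tok))
        if node.feature_id is not None:
            raise TaxonomyError(
                f"features {node.feature_id!r} and {fid!r} share the full "
                f"lineage {';'.join(tokens)!r}"
            )
        if node.children:
            raise TaxonomyError(
                f"feature {fid!r} claims leaf status at internal path "
                f"{';'.join(tokens)!r}"
            )
        node.feature_id = fid

    root = _to_nodes(trie, parent=None)
    root.name = "root"
    _compress_chains(root)
    return _finalize(root)


def _to_nodes(t: _Trie, parent: TaxNode | None) -> TaxNode:
    node = TaxNode(node_id="", name=t.name, parent=parent, feature_id=t.feature_id)
    node.children = [
        _to_nodes(t.children[k], node) for k in sorted(t.children)
    ]
    return node


def _compress_chains(node: TaxNode) -> None:
    """Collapse single-child chains top-down; the surviving node keeps the
    topmost position and concatenates names with ``|``."""
    while len(node.children) == 1:
        child = node.children[0]
        if child.is_leaf:
            if node.parent is None:
                break  # a lone feature under the root stays a leaf under root
            child.name = f"{node.name}|{child.name}"
            child.parent = node.parent
            node.parent.children[node.parent.children.index(node)] = child
            node = child
            break
        node.name = f"{node.name}|{child.name}"
        node.children = child.children
        for c in node.children:
            c.parent = node
    for c in node.children:
        _compress_chains(c)


def _finalize(root: TaxNode) -> TaxTree:
    """Assign depths, ids and leaf sets; register nodes."""
    nodes: dict[str, TaxNode] = {}

    def visit(node: TaxNode, depth: int) -> tuple[str, ...]:
        node.rank_depth = depth
        if node.is_leaf:
            assert node.feature_id is not None
            node.node_id = node.feature_id
            node.leaf_ids = (node.feature_id,)
        else:
            node.node_id = ROOT_ID if node.parent is None else ";".join(node.path())
            acc: list[str] = []
            for c in node.children:
                acc.extend(visit(c, depth + 1))
            node.leaf_ids = tuple(acc)
        if node.node_id in nodes:
            raise TaxonomyError(f"duplicate node id {node.node_id!r}")
        nodes[node.node_id] = node
        return node.leaf_ids

    visit(root, 0)
    return TaxTree(root=root, nodes=nodes, n_leaves=len(root.leaf_ids))


# ---------------------------------------------------------------------------
# aggregation and collapsing
# ---------------------------------------------------------------------------

def aggregate(tree: TaxTree, table: AbundanceTable) -> dict[str, np.ndarray]:
    """Per-node aggregated abundance vectors, one value per sample.

    Internal nodes carry the sum of their children's abundances; leaves carry
    the corresponding input feature column unchanged.
    """
    tree_leaves = tree.leaf_feature_ids()
    table_feats = set(table.feature_ids)
    if tree_leaves != table_feats:
        missing = sorted(tree_leaves - table_feats)
        extra = sorted(table_feats - tree_leaves)
        raise TaxonomyError(
            f"tree/table feature mismatch: {len(missing)} only in tree "
            f"{missing[:5]}, {len(extra)} only in table {extra[:5]}"
        )
    out: dict[str, np.ndarray] = {}

    def visit(node: TaxNode) -> np.ndarray:
        if node.is_leaf:
            vec = table.values[:, table.feature_index(node.feature_id)].copy()
        else:
            vec = np.zeros(table.n_samples)
            for c in node.children:
                vec += visit(c)
        out[node.node_id] = vec
        return vec

    visit(tree.root)
    return out


def collapse_to_level(tree: TaxTree, depth: int) -> list[str]:
    """The frontier at ``depth``: node ids at that rank depth, plus any leaf
    that sits shallower. The frontier's leaf sets partition all leaves.

    ``depth`` beyond the deepest rank simply returns every leaf.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    frontier: list[str] = []

    def visit(node: TaxNode) -> None:
        if node.rank_depth == depth or (node.is_leaf and node.rank_depth < depth):
            frontier.append(node.node_id)
            return
        for c in node.children:
            visit(c)

    visit(tree.root)
    return frontier


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def to_newick(tree: TaxTree, path=None) -> str:
    """Serialize as Newick (labels quoted where needed, no branch lengths)."""
    from skbio import TreeNode  # deferred: skbio import is slow

    def convert(node: TaxNode) -> TreeNode:
        return TreeNode(
            name=node.name, children=[convert(c) for c in node.children]
        )

    sk = convert(tree.root)
    buf = io.StringIO()
    sk.write(buf)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
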