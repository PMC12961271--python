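"""The expansion loop: seed a frontier of coarse clades, test each queued
clade once with the collapsed-vs-expanded AIC comparison, Wald-prune
uninformative children, and emit the surviving clades as the feature set.

Properties the loop guarantees (and the test suite asserts):

* each internal node is evaluated at most once, so the number of model
  comparisons is bounded by the internal-node count — work is linear in the
  number of input features;
* no selected feature is an ancestor of another (each microbe contributes
  its abundance to exactly one feature);
* decisions are local to a node, so the result is independent of queue
  discipline; FIFO is used for a readable audit log.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field, asdict

import numpy as np

from .stats import compare_models
from .table import AbundanceTable
from .taxonomy import TaxNode, TaxTree, aggregate, build_tree, collapse_to_level

__all__ = [
    "TagineConfig",
    "NodeDecision",
    "FeatureRecord",
    "FeatureSet",
    "run_tagine",
    "prune_tree",
    "transform",
]


@dataclass
class TagineConfig:
    """Tunable knobs of the expansion loop.

    start_depth:
        Taxonomic depth of the initial frontier (1 = one level below the
        root, the default).
    alpha:
        Wald significance level for pruning children of an expanded node.
    use_log_abundance:
        Fit regressions on log abundances (safe after the pseudocount step)
        instead of raw relative abundances.
    on_all_children_pruned:
        What to do when the AIC favours expansion but every child fails the
        Wald test: ``keep_collapsed`` (default) retains the clade as a single
        feature — the AIC verdict established that the clade carries signal
        even if individual coefficients are unstable; ``drop_node`` discards
        the clade entirely.
    """

    start_depth: int = 1
    alpha: float = 0.05
    use_log_abundance: bool = False
    use_aicc: bool = False
    child_p_adjust: str = "none"
    tie_rule: str = "keep_collapsed"
    on_all_children_pruned: str = "keep_collapsed"
    queue_discipline: str = "fifo"  # decisions are local, so fifo == lifo
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_depth < 1:
            raise ValueError("start_depth must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.on_all_children_pruned not in ("keep_collapsed", "drop_node"):
            raise ValueError(
                f"unknown on_all_children_pruned {self.on_all_children_pruned!r}"
            )
        if self.tie_rule != "keep_collapsed":
            raise ValueError("the only supported tie rule is 'keep_collapsed'")
        if self.queue_discipline not in ("fifo", "lifo"):
            raise ValueError("queue_discipline must be 'fifo' or 'lifo'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NodeDecision:
    """Audit record of one queue step."""

    node_id: str
    n_children: int
    aic_collapsed: float
    aic_expanded: float
    expanded: bool
    pruned_children: list[str] = field(default_factory=list)
    fallback_reason: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FeatureRecord:
    """One selected clade: identity, position and the leaves it aggregates."""

    node_id: str
    taxonomic_path: str
    rank_depth: int
    leaf_ids: tuple[str, ...]


@dataclass
class FeatureSet:
    """Final output: selected clades, their aggregated abundances on the
    training samples, and the full decision log."""

    features: list[FeatureRecord]
    matrix: np.ndarray  # samples x selected features
    sample_ids: list[str]
    decisions: list[NodeDecision]
    config: TagineConfig
    n_compare_calls: int = 0
    n_logistic_fits: int = 0

    @property
    def feature_ids(self) -> list[str]:
        return [f.node_id for f in self.features]

    def __len__(self) -> int:
        return len(self.features)


def _make_record(node: TaxNode) -> FeatureRecord:
    return FeatureRecord(
        node_id=node.node_id,
        taxonomic_path=";".join(node.path()) if node.parent is not None else node.name,
        rank_depth=node.rank_depth,
        leaf_ids=node.leaf_ids,
    )


def run_tagine(
    tree: TaxTree,
    table: AbundanceTable,
    y: np.ndarray,
    config: TagineConfig | None = None,
) -> FeatureSet:
    """Run the expansion loop and return the selected feature set.

    ``table`` should already be preprocessed (strictly positive relative
    abundances); ``y`` is the binary label vector aligned to the table's
    samples. The queue starts with the frontier at ``config.start_depth``;
    a popped leaf is emitted directly (it has no children to compare), and a
    popped internal node is either kept collapsed as a feature or expanded,
    in which case its Wald-pruned children are removed from consideration
    and the surviving children are enqueued (internal) or emitted (leaves).
    """
    config = config or TagineConfig()
    y = np.asarray(y, dtype=float).ravel()
    if y.size != table.n_samples:
        raise ValueError(f"y has {y.size} entries for {table.n_samples} samples")
    if np.unique(y).size != 2:
        raise ValueError("y must contain both classes")

    agg = aggregate(tree, table)
    queue: deque[str] = deque(collapse_to_level(tree, config.start_depth))
    features: list[FeatureRecord] = []
    decisions: list[NodeDecision] = []
    n_calls = 0
    n_fits = 0

    pop = queue.popleft if config.queue_discipline == "fifo" else queue.pop
    while queue:
        node = tree.nodes[pop()]
        if node.is_leaf:
            features.append(_make_record(node))
            continue
        children = node.children
        cmp = compare_models(
            agg[node.node_id],
            np.column_stack([agg[c.node_id] for c in children]),
            y,
            alpha=config.alpha,
            use_log=config.use_log_abundance,
            use_aicc=config.use_aicc,
            child_p_adjust=config.child_p_adjust,
        )
        n_calls += 1
        n_fits += cmp.n_fits

        if not cmp.expand:
            features.append(_make_record(node))
            decisions.append(NodeDecision(
                node_id=node.node_id, n_children=len(children),
                aic_collapsed=cmp.aic_collapsed, aic_expanded=cmp.aic_expanded,
                expanded=False, fallback_reason=cmp.fallback_reason,
            ))
            continue

        surviving = [c for c, s in zip(children, cmp.significant_children) if s]
        pruned = [c.node_id for c, s in zip(children, cmp.significant_children)
                  if not s]
        fallback = None
        if not surviving:
            fallback = f"all_children_pruned:{config.on_all_children_pruned}"
            if config.on_all_children_pruned == "keep_collapsed":
                features.append(_make_record(node))
        else:
            for c in surviving:
                if c.is_leaf:
                    features.append(_make_record(c))
                else:
                    queue.append(c.node_id)
        decisions.append(NodeDecision(
            node_id=node.node_id, n_children=len(children),
            aic_collapsed=cmp.aic_collapsed, aic_expanded=cmp.aic_expanded,
            expanded=True, pruned_children=pruned, fallback_reason=fallback,
        ))

    if not features:
        warnings.warn("every feature was pruned; returning an empty feature set")
    matrix = (
        np.column_stack([agg[f.node_id] for f in features])
        if features else np.empty((table.n_samples, 0))
    )
    return FeatureSet(
        features=features, matrix=matrix, sample_ids=list(table.sample_ids),
        decisions=decisions, config=config,
        n_compare_calls=n_calls, n_logistic_fits=n_fits,
    )


def prune_tree(tree: TaxTree, decisions: list[NodeDecision]) -> TaxTree:
    """Rebuild the taxonomy with everything the run discarded removed: the
    descendants of clades kept collapsed, and the subtrees of Wald-pruned
    children. The leaves of the result are exactly the selected features."""
    drop: set[str] = set()          # roots of removed subtrees
    make_leaf: set[str] = set()     # nodes whose descendants are removed
    for d in decisions:
        if not d.expanded:
            make_leaf.add(d.node_id)
        else:
            drop.update(d.pruned_children)
            if d.fallback_reason == "all_children_pruned:keep_collapsed":
                make_leaf.add(d.node_id)
            elif d.fallback_reason == "all_children_pruned:drop_node":
                drop.add(d.node_id)

    def copy(node: TaxNode, parent: TaxNode | None) -> TaxNode | None:
        if node.node_id in drop:
            return None
        new = TaxNode(
            node_id=node.node_id, name=node.name, rank_depth=node.rank_depth,
            parent=parent, feature_id=node.feature_id,
        )
        if node.node_id not in make_leaf:
            new.children = [
                c2 for c in node.children
                if (c2 := copy(c, new)) is not None
            ]
        new.leaf_ids = (
            node.leaf_ids if (new.is_leaf and node.node_id in make_leaf)
            else (node.leaf_ids if new.is_leaf else
                  tuple(lid for c in new.children for lid in c.leaf_ids))
        )
        return new

    root = copy(tree.root, None)
    assert root is not None
    nodes = {}

    def register(n: TaxNode) -> None:
        nodes[n.node_id] = n
        for c in n.children:
            register(c)

    register(root)
    return TaxTree(root=root, nodes=nodes, n_leaves=len(root.leaf_ids))


def transform(
    new_table: AbundanceTable,
    feature_set: FeatureSet,
    tree: TaxTree,
) -> np.ndarray:
    """Apply a learned clade grouping to held-out samples.

    Each output column is the sum of the new samples' abundances over the
    leaves captured for that feature at training time; abundances of leaves
    that were pruned during training are excluded, not re-added elsewhere.
    """
    tree_leaves = tree.leaf_feature_ids()
    extra = sorted(set(new_table.feature_ids) - tree_leaves)
    if extra:
        raise ValueError(
            f"{len(extra)} feature(s) unknown to the training taxonomy: {extra[:5]}"
        )
    have = set(new_table.feature_ids)
    out = np.zeros((new_table.n_samples, len(feature_set.features)))
    for j, feat in enumerate(feature_set.features):
        idx = [new_table.feature_index(l) for l in feat.leaf_ids if l in have]
        if idx:
            out[:, j] = new_table.values[:, idx].sum(axis=1)
    return out
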