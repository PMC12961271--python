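"""Independent reference implementations used as test oracles.

Everything here is deliberately written without importing the package's own
estimation or traversal code: logistic fits go through statsmodels, the
clade-expansion reference is a plain top-down recursion, the lineage oracle
is a dict-of-dicts trie, and BH is hand-coded from the step-up definition.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm


def sm_logit(X: np.ndarray, y: np.ndarray):
    """Unpenalized logistic fit via statsmodels; returns the Results object."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(y, design, family=sm.families.Binomial()).fit()


def sm_aic(X, y) -> float:
    res = sm_logit(X, y)
    return float(2 * len(res.params) - 2 * res.llf)


def reference_tagine(tree, agg, y, alpha=0.05, start_depth=1):
    """Top-down recursive restatement of the expansion rules, fitting with
    statsmodels: expand a node iff the children-model AIC is strictly lower
    than the single-feature AIC, prune children with two-sided Wald p >=
    alpha, keep a fully-pruned expanded node collapsed. Returns the selected
    node ids as a set."""
    selected: set[str] = set()

    def frontier(node, depth):
        if node.rank_depth == depth or (node.is_leaf and node.rank_depth < depth):
            return [node]
        out = []
        for c in node.children:
            out.extend(frontier(c, depth))
        return out

    def fit_or_none(X):
        try:
            res = sm_logit(X, y)
        except Exception:
            return None
        if not np.all(np.isfinite(res.params)):
            return None
        return res

    def decide(node):
        if node.is_leaf:
            selected.add(node.node_id)
            return
        x_node = agg[node.node_id]
        x_children = np.column_stack([agg[c.node_id] for c in node.children])
        keep = np.flatnonzero(x_children.std(axis=0) > 0)
        if np.std(x_node) == 0:
            aic_col = 2 - 2 * float(
                sm.GLM(y, np.ones((len(y), 1)),
                       family=sm.families.Binomial()).fit().llf)
        else:
            res_col = fit_or_none(x_node)
            aic_col = 2 * len(res_col.params) - 2 * res_col.llf
        if keep.size == 0:
            selected.add(node.node_id)
            return
        res_exp = fit_or_none(x_children[:, keep])
        if res_exp is None:
            selected.add(node.node_id)
            return
        # separation guard mirroring the implementation's standardized-scale rule
        scaled = np.abs(res_exp.params[1:]) * x_children[:, keep].std(axis=0)
        if np.any(scaled > 30.0):
            selected.add(node.node_id)
            return
        aic_exp = 2 * len(res_exp.params) - 2 * res_exp.llf
        if not (aic_exp < aic_col):
            selected.add(node.node_id)
            return
        pvals = res_exp.pvalues[1:]
        surviving = [node.children[keep[i]] for i in range(keep.size)
                     if pvals[i] < alpha]
        if not surviving:
            selected.add(node.node_id)  # keep_collapsed policy
            return
        for c in surviving:
            decide(c)

    for node in frontier(tree.root, start_depth):
        decide(node)
    return selected


def trie_from_lineages(lineages):
    """Brute-force path trie: nested dicts keyed by token, features stored
    under the terminal key None."""
    root: dict = {}
    for fid, tokens in lineages.items():
        node = root
        for tok in tokens:
            node = node.setdefault(tok, {})
        node.setdefault(None, []).append(fid)
    return root


def trie_leaves_under(trie) -> set:
    out = set()
    for key, sub in trie.items():
        if key is None:
            out.update(sub)
        else:
            out |= trie_leaves_under(sub)
    return out


def bh_stepup(pvalues):
    """Hand-coded Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return np.minimum(q, 1.0)


def brute_force_filter(values, mean_min, prev_min):
    """Per-feature loop restatement of the rare-feature filter; returns the
    boolean keep mask for a samples x features matrix."""
    n, p = values.shape
    keep = np.zeros(p, dtype=bool)
    for j in range(p):
        col = values[:, j]
        mean = sum(col) / n
        prev = sum(1 for v in col if v > 0) / n
        keep[j] = (mean >= mean_min) and (prev >= prev_min)
    return keep
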