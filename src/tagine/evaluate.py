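"""Benchmarking protocol: repeated stratified train/test splits, downstream
random-forest AUC, and paired comparisons with the Nadeau-Bengio corrected
resampled t-test plus Benjamini-Hochberg FDR.

The corrected resampled t-test inflates the paired t-test's variance term by
``1/J + n_test/n_train`` (J = number of splits) to account for the overlap
between random train/test resamples, which makes the naive t-test badly
anti-conservative. The variant implemented here is the corrected resampled
t-test (not the conservative Z); p-values come from Student's t with J-1
degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from statsmodels.stats.multitest import multipletests

from .core import TagineConfig, run_tagine, transform
from .preprocess import apply_pipeline, preprocess_pipeline
from .table import AbundanceTable
from .taxonomy import aggregate, build_tree, collapse_to_level

__all__ = [
    "SplitPlan",
    "BenchmarkResult",
    "make_splits",
    "auc_roc",
    "nb_corrected_ttest",
    "bh_fdr",
    "benchmark",
]


@dataclass
class SplitPlan:
    """Seeded, class-stratified repeated train/test partitions."""

    n_repeats: int
    train_fraction: float
    seed: int
    assignments: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


@dataclass
class BenchmarkResult:
    """Per-repeat records plus pairwise corrected-t comparisons."""

    records: pd.DataFrame  # columns: method, repeat, auc, n_features, fit_count
    comparisons: pd.DataFrame  # method_a, method_b, metric, t, p, q

    def mean_auc(self, method: str) -> float:
        sub = self.records[self.records["method"] == method]
        return float(sub["auc"].mean())

    def mean_n_features(self, method: str) -> float:
        sub = self.records[self.records["method"] == method]
        return float(sub["n_features"].mean())


def make_splits(
    sample_ids: list[str],
    labels: np.ndarray,
    n_repeats: int = 50,
    train_fraction: float = 0.85,
    seed: int = 0,
) -> SplitPlan:
    """Class-stratified random partitions (default 50 repeats of 85%/15%)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need two classes with at least 2 samples each")
    sss = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_fraction, random_state=seed
    )
    assignments = []
    for train_idx, test_idx in sss.split(np.zeros(len(sample_ids)), labels):
        if np.unique(labels[train_idx]).size < 2:  # pragma: no cover
            raise ValueError("a training split lost a class")
        assignments.append((train_idx, test_idx))
    return SplitPlan(
        n_repeats=n_repeats, train_fraction=train_fraction, seed=seed,
        assignments=assignments,
    )


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC-ROC (Mann-Whitney construction, ties averaged)."""
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def nb_corrected_ttest(
    diffs: np.ndarray, n_train: int, n_test: int
) -> tuple[float, float]:
    """Corrected resampled t-test on paired per-split differences.

    t = mean(d) / sqrt((1/J + n_test/n_train) * var(d)), var unbiased;
    two-sided p from Student's t with J-1 df.
    """
    d = np.asarray(diffs, dtype=float)
    J = d.size
    if J < 2:
        raise ValueError("need at least 2 paired differences")
    m = d.mean()
    v = d.var(ddof=1)
    if v == 0:
        if m == 0:
            return 0.0, 1.0
        warnings.warn("zero variance with nonzero mean difference")
        return float(np.sign(m) * np.inf), 0.0
    t = m / np.sqrt((1.0 / J + n_test / n_train) * v)
    p = 2.0 * sps.t.sf(abs(t), df=J - 1)
    return float(t), float(p)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# full benchmark
# ---------------------------------------------------------------------------

def _method_features(method: str, train, test, tree, y_train, config, rng_seed):
    """Returns (X_train, X_test, n_features, fit_count) for one method on one
    preprocessed split. ``train``/``test`` are AbundanceTables restricted to
    the post-filter feature set; ``tree`` is built on those features."""
    if method == "tagine":
        fs = run_tagine(tree, train, y_train, config)
        return (fs.matrix, transform(test, fs, tree), len(fs),
                fs.n_logistic_fits)
    if method == "none":
        return train.values, test.values, train.n_features, 0
    if method == "all-levels":
        agg_tr = aggregate(tree, train)
        agg_te = aggregate(tree, test)
        ids = sorted(set(tree.nodes) - {tree.root.node_id})
        Xtr = np.column_stack([agg_tr[i] for i in ids])
        Xte = np.column_stack([agg_te[i] for i in ids])
        return Xtr, Xte, len(ids), 0
    if method.startswith("fixed-level:"):
        depth = int(method.split(":", 1)[1])
        frontier = collapse_to_level(tree, depth)
        agg_tr = aggregate(tree, train)
        agg_te = aggregate(tree, test)
        Xtr = np.column_stack([agg_tr[i] for i in frontier])
        Xte = np.column_stack([agg_te[i] for i in frontier])
        return Xtr, Xte, len(frontier), 0
    if method.startswith("rfe"):
        # optional convenience: off-the-shelf recursive feature elimination
        # over all taxonomic levels, matched to TAGINE's feature count
        n_target = int(method.split(":", 1)[1]) if ":" in method else 20
        from sklearn.svm import SVR

        agg_tr = aggregate(tree, train)
        agg_te = aggregate(tree, test)
        ids = sorted(set(tree.nodes) - {tree.root.node_id})
        Xtr = np.column_stack([agg_tr[i] for i in ids])
        Xte = np.column_stack([agg_te[i] for i in ids])
        sel = RFE(SVR(kernel="linear"), n_features_to_select=n_target,
                  step=0.1).fit(Xtr, y_train)
        return (Xtr[:, sel.support_], Xte[:, sel.support_],
                int(sel.support_.sum()), 0)
    raise ValueError(f"unknown method {method!r}")


def benchmark(
    methods: list[str],
    table: AbundanceTable,
    labels: np.ndarray,
    plan: SplitPlan | None = None,
    config: TagineConfig | None = None,
    n_repeats: int = 50,
    train_fraction: float = 0.85,
    seed: int = 0,
    n_trees: int = 500,
    mean_abundance_min: float = 1e-6,
    prevalence_min: float = 1e-2,
) -> BenchmarkResult:
    """Run the full protocol: per repeat, preprocess on the training samples
    only, run each feature-engineering method on the training set, project
    the held-out samples onto the selected features, score a random forest
    by AUC-ROC, then compare methods pairwise with the corrected resampled
    t-test and BH-FDR across all tests.
    """
    labels = np.asarray(labels)
    config = config or TagineConfig()
    if plan is None:
        plan = make_splits(table.sample_ids, labels, n_repeats,
                           train_fraction, seed)
    rows = []
    for r, (tr_idx, te_idx) in enumerate(plan.assignments):
        train_raw = table.select_samples(tr_idx)
        test_raw = table.select_samples(te_idx)
        y_tr, y_te = labels[tr_idx], labels[te_idx]
        train, report = preprocess_pipeline(
            train_raw, mean_abundance_min, prevalence_min)
        test = apply_pipeline(test_raw, report)
        tree = build_tree({f: table.lineages[f]
                           for f in report.kept_features})
        for method in methods:
            try:
                Xtr, Xte, n_feat, n_fit = _method_features(
                    method, train, test, tree, y_tr, config,
                    plan.seed + r)
            except Exception as exc:  # a method failing one repeat
                warnings.warn(f"{method} failed on repeat {r}: {exc}")
                continue
            clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=plan.seed + r, n_jobs=1
            ).fit(Xtr, y_tr)
            scores = clf.predict_proba(Xte)[:, 1]
            rows.append({
                "method": method, "repeat": r,
                "auc": auc_roc(scores, y_te),
                "n_features": n_feat, "fit_count": n_fit,
                "n_train": len(tr_idx), "n_test": len(te_idx),
            })
    records = pd.DataFrame(rows)
    comps = []
    for a, b in combinations(methods, 2):
        da = records[records["method"] == a].set_index("repeat")
        db = records[records["method"] == b].set_index("repeat")
        common = da.index.intersection(db.index)
        if len(common) < 2:
            continue
        if len(common) < len(plan.assignments):
            warnings.warn(
                f"comparison {a} vs {b} uses {len(common)} of "
                f"{len(plan.assignments)} repeats (method failures excluded)")
        diffs = (da.loc[common, "auc"] - db.loc[common, "auc"]).to_numpy()
        n_tr = int(da.loc[common, "n_train"].iloc[0])
        n_te = int(da.loc[common, "n_test"].iloc[0])
        t, p = nb_corrected_ttest(diffs, n_tr, n_te)
        comps.append({"method_a": a, "method_b": b, "metric": "auc",
                      "t": t, "p": p})
    comparisons = pd.DataFrame(comps)
    if len(comparisons):
        comparisons["q"] = bh_fdr(comparisons["p"].to_numpy())
    return BenchmarkResult(records=records, comparisons=comparisons)
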