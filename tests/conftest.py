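import numpy as np
import pytest

from tagine import (AbundanceTable, SyntheticSpec, build_tree,
                    preprocess_pipeline, simulate_dataset)


@pytest.fixture
def three_phyla_lineages():
    return {
        "f1": ["Bacteria", "Firmicutes", "Bacilli"],
        "f2": ["Bacteria", "Firmicutes", "Clostridia"],
        "f3": ["Bacteria", "Bacteroidota", "Bacteroidia"],
    }


@pytest.fixture
def small_dataset():
    """Preprocessed synthetic dataset with a depth-2 planted clade."""
    spec = SyntheticSpec(n_samples=200, n_species=80, ranks=4,
                         signal_node_depth=2, effect_size=3.0, seed=11)
    table, tree, signal = simulate_dataset(spec)
    table, report = preprocess_pipeline(table)
    tree = build_tree({f: table.lineages[f] for f in table.feature_ids})
    return table, tree, signal


def random_instance(rng, n_leaves=8, n_samples=80, max_ranks=4, signal=True):
    """A random small tree + preprocessed table + labels, for randomized
    property checks. Returns (table, tree, y)."""
    while True:  # redraw when sparsity wipes out a whole (tiny) sample
        spec = SyntheticSpec(
            n_samples=n_samples,
            n_species=n_leaves,
            ranks=int(rng.integers(2, max_ranks + 1)),
            branching=(2, 3),
            signal_node_depth=1,
            effect_size=float(rng.uniform(0, 3)) if signal else 0.0,
            sparsity=float(rng.uniform(0, 0.4)),
            seed=int(rng.integers(2**31 - 1)),
        )
        try:
            table, tree, sig = simulate_dataset(spec)
            break
        except ValueError:
            continue
    table, _ = preprocess_pipeline(table)
    tree = build_tree({f: table.lineages[f] for f in table.feature_ids})
    y = sig.y
    if np.unique(y).size < 2:  # pragma: no cover
        y = rng.integers(0, 2, size=table.n_samples)
    return table, tree, y
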