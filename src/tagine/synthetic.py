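"""Lineage-structured synthetic abundance tables with planted class signal.

The generator emulates the gross statistical shape of species-level
taxonomic profiles — a rank-balanced taxonomy, heavy-tailed (log-normal)
per-species abundances, random sparsity, compositional closure — and plants
a binary class signal on the aggregated abundance of one clade at a chosen
depth. Log-normal composition is used instead of a Dirichlet because it is
heavy-tailed like real profiles and its moments are directly checkable.

The signal is defined on the *standardized* clade aggregate: labels are
drawn as ``y ~ Bernoulli(sigmoid(effect_size * z))`` where ``z`` is the
z-score of the planted clade's aggregate across samples, so ``effect_size``
is a log-odds per standard deviation and recovery thresholds are stable
across table sizes and scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .table import AbundanceTable
from .taxonomy import TaxTree, aggregate

__all__ = ["SyntheticSpec", "PlantedSignal", "sample_taxonomy",
           "sample_abundances", "plant_signal", "simulate_dataset"]

_RANK_LETTERS = "kpcofgs"  # kingdom..species naming for generated tokens


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    branching is the (min, max) number of children per internal node; the
    taxonomy partitions ``n_species`` leaves into ``ranks`` levels with
    branching drawn uniformly from that range wherever feasible.
    """

    n_samples: int = 300
    n_species: int = 500
    ranks: int = 5
    branching: tuple[int, int] = (2, 5)
    signal_node_depth: int = 2
    effect_size: float = 3.0
    noise_model: str = "lognormal"
    log_mean: float = 0.0
    log_sd: float = 1.0
    sparsity: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.branching, int):
            self.branching = (self.branching, self.branching)
        self.branching = (int(self.branching[0]), int(self.branching[1]))
        if self.branching[0] < 2 or self.branching[1] < self.branching[0]:
            raise ValueError(f"invalid branching range {self.branching}")
        if not (0 <= self.sparsity < 1):
            raise ValueError("sparsity must be in [0, 1)")
        if self.signal_node_depth > self.ranks:
            raise ValueError("signal_node_depth cannot exceed ranks")
        if self.noise_model != "lognormal":
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")


@dataclass
class PlantedSignal:
    """Labels plus provenance of the clade the signal was planted on."""

    y: np.ndarray
    planted_node_id: str
    planted_depth: int
    effect_size: float


def sample_taxonomy(spec: SyntheticSpec) -> dict[str, tuple[str, ...]]:
    """Random rank-balanced lineages: every species sits at depth ``ranks``.

    Leaves are partitioned recursively; at each level a group of species is
    split into k child groups with k drawn from the branching range (capped
    by the group size). Deterministic under ``spec.seed``.
    """
    lo, hi = spec.branching
    if spec.n_species < lo:
        raise ValueError(
            f"n_species={spec.n_species} below minimum branching {lo}"
        )
    rng = np.random.default_rng(spec.seed)
    counters = [0] * spec.ranks
    lineages: dict[str, tuple[str, ...]] = {}

    def grow(indices: np.ndarray, depth: int, prefix: tuple[str, ...]) -> None:
        if depth == spec.ranks - 1:
            # final rank: one token per species
            for i in indices:
                counters[depth] += 1
                tok = f"{_RANK_LETTERS[depth % len(_RANK_LETTERS)]}__t{counters[depth]}"
                lineages[f"sp{i:05d}"] = prefix + (tok,)
            return
        size = len(indices)
        k = min(int(rng.integers(lo, hi + 1)), size)
        groups = np.array_split(indices, k)
        for g in groups:
            counters[depth] += 1
            tok = f"{_RANK_LETTERS[depth % len(_RANK_LETTERS)]}__t{counters[depth]}"
            grow(g, depth + 1, prefix + (tok,))

    grow(np.arange(spec.n_species), 0, ())
    return lineages


def sample_abundances(
    lineages: dict[str, tuple[str, ...]],
    spec: SyntheticSpec,
    normalize: bool = True,
) -> AbundanceTable:
    """Log-normal species abundances with random zeros, closed to sum one.

    With ``normalize=False`` the raw (open) log-normal draws are returned,
    which is what moment checks on ``log_mean``/``log_sd`` should use.
    """
    rng = np.random.default_rng(spec.seed + 1)
    feature_ids = sorted(lineages)
    n, p = spec.n_samples, len(feature_ids)
    values = rng.lognormal(spec.log_mean, spec.log_sd, size=(n, p))
    if spec.sparsity > 0:
        values *= rng.random(size=(n, p)) >= spec.sparsity
        dead = np.flatnonzero(values.sum(axis=1) == 0)
        if dead.size:  # resample all-zero rows once
            values[dead] = rng.lognormal(spec.log_mean, spec.log_sd,
                                         size=(dead.size, p))
            values[dead] *= rng.random(size=(dead.size, p)) >= spec.sparsity
            if np.any(values[dead].sum(axis=1) == 0):
                raise ValueError("sparsity too high: all-zero sample persists")
    if normalize:
        values = values / values.sum(axis=1)[:, None]
    return AbundanceTable(
        sample_ids=[f"s{i:04d}" for i in range(n)],
        feature_ids=feature_ids,
        values=values,
        lineages=lineages,
    )


def plant_signal(
    table: AbundanceTable,
    tree: TaxTree,
    spec: SyntheticSpec,
) -> PlantedSignal:
    """Pick one clade at ``signal_node_depth`` and draw labels from a
    logistic model on its standardized aggregated abundance."""
    rng = np.random.default_rng(spec.seed + 2)
    candidates = sorted(
        nid for nid, node in tree.nodes.items()
        if node.rank_depth == spec.signal_node_depth
    )
    if not candidates:
        raise ValueError(f"no node at depth {spec.signal_node_depth}")
    node_id = candidates[int(rng.integers(len(candidates)))]
    agg = aggregate(tree, table)[node_id]
    sd = agg.std()
    z = (agg - agg.mean()) / sd if sd > 0 else np.zeros_like(agg)
    prob = 1.0 / (1.0 + np.exp(-spec.effect_size * z))
    y = (rng.random(table.n_samples) < prob).astype(int)
    if np.unique(y).size < 2:  # pathological draw; flip one label
        y[0] = 1 - y[0]
    return PlantedSignal(
        y=y, planted_node_id=node_id,
        planted_depth=spec.signal_node_depth, effect_size=spec.effect_size,
    )


def simulate_dataset(spec: SyntheticSpec):
    """Convenience: taxonomy + abundances + tree + planted labels."""
    from .taxonomy import build_tree

    lineages = sample_taxonomy(spec)
    table = sample_abundances(lineages, spec)
    tree = build_tree(lineages)
    signal = plant_signal(table, tree, spec)
    return table, tree, signal
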