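"""Compositional preprocessing: rare-feature filtering, relative-abundance
normalization, and per-sample half-minimum pseudocounts.

The default pipeline order is

    normalize -> filter (train-set statistics) -> renormalize
              -> pseudocount -> renormalize

Filtering on the relative scale keeps the mean-abundance threshold (1e-6)
meaningful for raw-count input; ``filter_on="raw"`` restores a literal
filter-before-normalization order for data already on a common scale.

The per-sample pseudocount is half the smallest *strictly positive* value in
that sample: half of an exact zero would be a no-op and leave zeros in place,
defeating the purpose of the step. "Prevalence" is the fraction of (training)
samples in which a feature is non-zero.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .table import AbundanceTable

__all__ = [
    "FilterReport",
    "filter_rare",
    "normalize_relative",
    "add_pseudocount",
    "preprocess_pipeline",
    "apply_pipeline",
]


@dataclass
class FilterReport:
    """Accounting for one rare-feature filtering pass.

    A feature can fail both criteria, so the removed *set* (union), not the
    sum of the two counters, complements ``n_kept``.
    """

    n_input: int
    n_removed_abundance: int
    n_removed_prevalence: int
    n_kept: int
    mean_abundance_min: float
    prevalence_min: float
    kept_features: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kept_features"] = list(self.kept_features)
        return d


def normalize_relative(table: AbundanceTable) -> AbundanceTable:
    """Scale each sample to sum to one (relative abundances)."""
    totals = table.values.sum(axis=1)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        names = [table.sample_ids[i] for i in bad[:5]]
        raise ValueError(f"zero-total sample(s), cannot normalize: {names}")
    return table.with_values(table.values / totals[:, None])


def filter_rare(
    table: AbundanceTable,
    mean_abundance_min: float = 1e-6,
    prevalence_min: float = 1e-2,
) -> tuple[AbundanceTable, FilterReport]:
    """Drop features with mean abundance below ``mean_abundance_min`` or
    prevalence (fraction of samples with a non-zero value) below
    ``prevalence_min``, computed on *this* table — pass the training subset
    and re-apply the kept list to held-out data via ``select_features``.
    """
    means = table.values.mean(axis=0)
    prev = (table.values > 0).mean(axis=0)
    fail_abund = means < mean_abundance_min
    fail_prev = prev < prevalence_min
    keep_mask = ~(fail_abund | fail_prev)
    kept = [f for f, k in zip(table.feature_ids, keep_mask) if k]
    if not kept:
        raise ValueError(
            "rare-feature filter removed every feature; relax "
            f"mean_abundance_min={mean_abundance_min} or "
            f"prevalence_min={prevalence_min}"
        )
    report = FilterReport(
        n_input=table.n_features,
        n_removed_abundance=int(fail_abund.sum()),
        n_removed_prevalence=int(fail_prev.sum()),
        n_kept=len(kept),
        mean_abundance_min=mean_abundance_min,
        prevalence_min=prevalence_min,
        kept_features=tuple(kept),
    )
    return table.select_features(kept), report


def add_pseudocount(table: AbundanceTable) -> AbundanceTable:
    """Add half of each sample's minimum positive value to every feature of
    that sample, then renormalize the sample to sum to one.

    The output is strictly positive and preserves each sample's within-sample
    rank order of features.
    """
    v = table.values
    masked = np.where(v > 0, v, np.inf)
    min_pos = masked.min(axis=1)
    bad = np.flatnonzero(~np.isfinite(min_pos))
    if bad.size:
        names = [table.sample_ids[i] for i in bad[:5]]
        raise ValueError(f"all-zero sample(s), cannot add pseudocount: {names}")
    shifted = v + 0.5 * min_pos[:, None]
    return table.with_values(shifted / shifted.sum(axis=1)[:, None])


def preprocess_pipeline(
    table: AbundanceTable,
    mean_abundance_min: float = 1e-6,
    prevalence_min: float = 1e-2,
    filter_on: str = "relative",
) -> tuple[AbundanceTable, FilterReport]:
    """Full training-side pipeline; the returned report carries the kept
    feature list needed to apply the same filter to held-out samples."""
    if filter_on not in ("relative", "raw"):
        raise ValueError(f"filter_on must be 'relative' or 'raw', got {filter_on!r}")
    if filter_on == "relative":
        table = normalize_relative(table)
    table, report = filter_rare(table, mean_abundance_min, prevalence_min)
    table = normalize_relative(table)
    return add_pseudocount(table), report


def apply_pipeline(table: AbundanceTable, report: FilterReport,
                   filter_on: str = "relative") -> AbundanceTable:
    """Apply a training-derived filter to new samples.

    Only the kept-feature list crosses over from training; normalization and
    the pseudocount are per-sample operations, so no held-out statistics leak
    into training and vice versa.
    """
    if filter_on == "relative":
        table = normalize_relative(table)
    table = table.select_features(list(report.kept_features))
    table = normalize_relative(table)
    return add_pseudocount(table)
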