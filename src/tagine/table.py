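"""Sample-by-feature abundance container with taxonomic lineage metadata.

The table is always held samples x features internally; readers that accept
the common features-as-rows microbiome layout transpose at parse time (see
:mod:`tagine.io`), controlled by an explicit orientation flag, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable"]


@dataclass
class AbundanceTable:
    """Non-negative abundance matrix plus per-feature lineages.

    Parameters
    ----------
    sample_ids:
        Unique sample identifiers, one per matrix row.
    feature_ids:
        Unique feature (taxon) identifiers, one per matrix column.
    values:
        ``(n_samples, n_features)`` array of non-negative abundances
        (raw counts or relative abundances).
    lineages:
        Maps each feature id to its ordered lineage tokens, coarsest rank
        first (e.g. ``("k__Bacteria", "p__Firmicutes", ...)``).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        n_s, n_f = self.values.shape
        if n_s != len(self.sample_ids) or n_f != len(self.feature_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != n_f:
            raise ValueError("duplicate feature ids")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("abundances must be finite and non-negative")
        self.lineages = {
            str(k): tuple(str(t) for t in v) for k, v in self.lineages.items()
        }

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self._findex[feature_id]
        except AttributeError:
            self._findex = {f: i for i, f in enumerate(self.feature_ids)}
            return self._findex[feature_id]

    # -- subsetting ------------------------------------------------------
    def select_features(self, keep: Sequence[str]) -> "AbundanceTable":
        """Return a copy restricted to ``keep`` (order preserved as given)."""
        idx = [self.feature_index(f) for f in keep]
        return AbundanceTable(
            sample_ids=list(self.sample_ids),
            feature_ids=list(keep),
            values=self.values[:, idx].copy(),
            lineages={f: self.lineages[f] for f in keep if f in self.lineages},
        )

    def select_samples(self, keep: Sequence[str] | np.ndarray) -> "AbundanceTable":
        """Return a copy restricted to the given sample ids or integer index."""
        arr = np.asarray(keep)
        if arr.dtype.kind in "iub":
            idx = arr.astype(int)
            ids = [self.sample_ids[i] for i in idx]
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            ids = [str(s) for s in keep]
            idx = np.array([pos[s] for s in ids])
        return AbundanceTable(
            sample_ids=ids,
            feature_ids=list(self.feature_ids),
            values=self.values[idx, :].copy(),
            lineages=dict(self.lineages),
        )

    def with_values(self, values: np.ndarray) -> "AbundanceTable":
        return AbundanceTable(
            sample_ids=list(self.sample_ids),
            feature_ids=list(self.feature_ids),
            values=values,
            lineages=dict(self.lineages),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        lineages: Mapping[str, Sequence[str]] | None = None,
    ) -> "AbundanceTable":
        """Build from a samples x features DataFrame."""
        return cls(
            sample_ids=[str(s) for s in df.index],
            feature_ids=[str(f) for f in df.columns],
            values=df.to_numpy(dtype=float),
            lineages={k: tuple(v) for k, v in (lineages or {}).items()},
        )
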