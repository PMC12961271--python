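"""Readers and writers for the on-disk formats: lineage-annotated abundance
TSVs, sample metadata tables, and run outputs (features TSV, Newick tree,
decision log JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FeatureSet
from .preprocess import FilterReport
from .table import AbundanceTable

__all__ = [
    "read_lineage_table",
    "read_metadata_labels",
    "write_feature_table",
    "write_decisions_json",
    "write_lineage_table",
]


def parse_lineage(text: str, sep: str = ";") -> tuple[str, ...]:
    """Split a lineage string into tokens, keeping rank prefixes verbatim."""
    return tuple(tok.strip() for tok in str(text).split(sep) if tok.strip() != "")


def read_lineage_table(
    path,
    orientation: str = "features-as-rows",
    lineage_col: str = "lineage",
    lineage_sep: str = ";",
    delimiter: str = "\t",
) -> AbundanceTable:
    """Read an abundance TSV whose first column is the feature id, with a
    ``lineage`` column of separator-joined rank tokens; every remaining
    column is a sample.

    ``orientation`` must be stated explicitly: ``features-as-rows`` (the
    common microbiome layout, transposed on read) or ``samples-as-rows``
    (requires per-feature lineages supplied another way, so only
    features-as-rows carries lineages).
    """
    if orientation not in ("features-as-rows", "samples-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if orientation == "features-as-rows":
        if lineage_col not in df.columns:
            raise ValueError(
                f"no {lineage_col!r} column in {path}; columns: "
                f"{list(df.columns)[:5]}"
            )
        lineages = {
            str(fid): parse_lineage(lin, lineage_sep)
            for fid, lin in df[lineage_col].items()
        }
        data = df.drop(columns=[lineage_col]).T  # now samples x features
        return AbundanceTable.from_dataframe(data.astype(float), lineages)
    lineages = {}
    if lineage_col in df.columns:
        raise ValueError(
            "samples-as-rows layout cannot carry a per-feature lineage column"
        )
    return AbundanceTable.from_dataframe(df.astype(float), lineages)


def read_metadata_labels(path, label_col: str, delimiter: str | None = None):
    """Read sample metadata (sample id in the first column) and return a
    ``sample_id -> binary label`` mapping. Non-numeric labels are encoded
    0/1 by sorted order, which is reported back alongside the mapping."""
    sep = delimiter or ("," if str(path).endswith(".csv") else "\t")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if label_col not in df.columns:
        raise ValueError(f"no column {label_col!r} in {path}")
    raw = df[label_col]
    levels = sorted(raw.dropna().unique(), key=str)
    if len(levels) != 2:
        raise ValueError(
            f"label column {label_col!r} has {len(levels)} levels; need 2"
        )
    mapping = {lv: i for i, lv in enumerate(levels)}
    labels = {str(s): int(mapping[v]) for s, v in raw.dropna().items()}
    return labels, {str(k): v for k, v in mapping.items()}


def write_lineage_table(table: AbundanceTable, path, lineage_sep: str = ";"):
    """Write the features-as-rows TSV layout (inverse of the reader)."""
    df = table.to_dataframe().T
    df.insert(0, "lineage",
              [lineage_sep.join(table.lineages.get(f, (f,)))
               for f in df.index])
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def write_feature_table(feature_set: FeatureSet, path) -> None:
    """Selected features x samples TSV with the taxonomic path and depth."""
    df = pd.DataFrame(
        feature_set.matrix.T,
        index=[f.node_id for f in feature_set.features],
        columns=feature_set.sample_ids,
    )
    df.insert(0, "rank_depth", [f.rank_depth for f in feature_set.features])
    df.insert(0, "taxonomic_path",
              [f.taxonomic_path for f in feature_set.features])
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def write_decisions_json(
    feature_set: FeatureSet,
    path,
    filter_report: FilterReport | None = None,
) -> None:
    """Full audit record: config, per-node decisions, selected features and
    (when available) the preprocessing filter report."""
    payload = {
        "config": feature_set.config.to_dict(),
        "n_compare_calls": feature_set.n_compare_calls,
        "n_logistic_fits": feature_set.n_logistic_fits,
        "n_features": len(feature_set),
        "features": [
            {"node_id": f.node_id, "taxonomic_path": f.taxonomic_path,
             "rank_depth": f.rank_depth, "n_leaves": len(f.leaf_ids)}
            for f in feature_set.features
        ],
        "decisions": [d.to_dict() for d in feature_set.decisions],
    }
    if filter_report is not None:
        rep = filter_report.to_dict()
        rep.pop("kept_features", None)
        payload["filter_report"] = rep
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
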