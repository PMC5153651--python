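"""Readers and writers: CSV peak tables and metadata, result artifacts, Newick trees.

CSV follows RFC-4180 quoting via pandas. ROC curves are written as TSV,
groupings as JSON, dendrograms additionally as Newick with method names as
leaves and merge-height differences as branch lengths.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import NormalizedTable, PeakTable, SampleMetadata

DEFAULT_MISSING_CODES = ("", "NA", "NaN")


def read_peak_table(
    path,
    dialect: str = "features_in_rows",
    missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
) -> PeakTable:
    """Read a peak-intensity CSV into the canonical features-in-rows orientation.

    The first column holds IDs (features or samples depending on ``dialect``).
    Cells matching one of ``missing_codes`` are flagged missing. Zero is NOT
    treated as missing unless "0" is listed explicitly, because zeros may be
    genuine low signals.
    """
    if dialect not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown dialect: {dialect}")
    codes = {str(c) for c in missing_codes}
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate IDs in first column: {sorted(set(df.index[df.index.duplicated()]))}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate IDs in header: {sorted(set(df.columns[df.columns.duplicated()]))}")

    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    mask = np.zeros(raw.shape, dtype=bool)
    for (r, c), cell in np.ndenumerate(raw):
        cell = cell.strip()
        if cell in codes:
            values[r, c] = np.nan
            mask[r, c] = True
            continue
        try:
            v = float(cell)
        except ValueError:
            raise ValueError(
                f"non-numeric cell {cell!r} at row {df.index[r]!r}, column {df.columns[c]!r}"
            ) from None
        if v < 0:
            raise ValueError(f"negative intensity {v} at row {df.index[r]!r}, column {df.columns[c]!r}")
        values[r, c] = v

    if dialect == "samples_in_rows":
        values, mask = values.T, mask.T
        feature_ids, sample_ids = list(df.columns), list(df.index)
    else:
        feature_ids, sample_ids = list(df.index), list(df.columns)
    return PeakTable(feature_ids, sample_ids, values, mask)


def write_peak_table(table: PeakTable, path) -> None:
    table.to_dataframe().to_csv(path)


def read_metadata(path) -> SampleMetadata:
    """Read a sample-metadata CSV (sample_id, class[, role, batch, order])."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    rename = {"class": "class_label", "order": "injection_order"}
    df = df.rename(columns=rename)
    if "sample_id" not in df.columns or "class_label" not in df.columns:
        raise ValueError("metadata CSV requires columns 'sample_id' and 'class'")
    if "role" not in df.columns:
        df["role"] = "study"
    if "batch" not in df.columns:
        df["batch"] = 1
    if "injection_order" not in df.columns:
        df["injection_order"] = np.arange(1, len(df) + 1)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.df.reset_index(drop=True).to_csv(path, index=False)


def write_normalized(table: NormalizedTable, path) -> None:
    table.to_dataframe().to_csv(path)


def read_normalized(path, method: str = "unknown", scale: str = "raw") -> NormalizedTable:
    df = pd.read_csv(path, index_col=0)
    return NormalizedTable(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(), method, scale)


def write_roc(result, path) -> None:
    """Write ROC points of an EvaluationResult as TSV (fpr, tpr, threshold)."""
    df = pd.DataFrame(result.roc_points, columns=["fpr", "tpr", "threshold"])
    df.to_csv(path, sep="\t", index=False)


def write_evaluation(result, out_dir, prefix: str = "result") -> list[str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    p = os.path.join(out_dir, f"{prefix}.json")
    with open(p, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    paths.append(p)
    p = os.path.join(out_dir, f"{prefix}_roc.tsv")
    write_roc(result, p)
    paths.append(p)
    return paths


def linkage_to_newick(linkage: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick string.

    Branch lengths are differences between a node's merge height and its
    children's heights (leaves sit at height 0).
    """
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(np.asarray(linkage, dtype=float))

    def label(name: str) -> str:
        # quote so underscores survive the Newick unquoted-label convention
        if any(c in name for c in " _():;,'\""):
            return "'" + name.replace("'", "''") + "'"
        return name

    def recurse(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{label(leaf_names[node.id])}:{length:.10g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    body = recurse(tree, tree.dist)
    # strip the root's zero-length suffix
    body = body.rsplit(":", 1)[0]
    return body + ";"


def write_grouping(grouping, out_dir, prefix: str = "grouping") -> list[str]:
    """Write a MethodGrouping as JSON plus a Newick dendrogram."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    p = os.path.join(out_dir, f"{prefix}.json")
    with open(p, "w") as fh:
        json.dump(grouping.to_dict(), fh, indent=2)
    paths.append(p)
    p = os.path.join(out_dir, "dendrogram.nwk")
    with open(p, "w") as fh:
        fh.write(linkage_to_newick(grouping.linkage, grouping.methods) + "\n")
    paths.append(p)
    return paths


def write_auc_matrix(methods, fractions, auc_matrix, path) -> None:
    df = pd.DataFrame(auc_matrix, index=methods, columns=[f"{f:g}" for f in fractions])
    df.to_csv(path)
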