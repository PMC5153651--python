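"""Benchmark engine: sub-dataset generation, the methods x sizes AUC matrix,
and sample-size-dependent categorization of the normalization methods.

Sub-datasets of growing size (10% ... 100% of the training samples, class
ratio preserved) are drawn per class from k-means strata so every region of
the sample space stays represented at every size. Each (method, sub-dataset)
cell is scored on one fixed validation set normalized with references frozen
on that cell's training samples. Each method's 10-dimensional AUC vector is
then clustered (Manhattan or Euclidean distance, Ward linkage) and the k=3
cut is ranked by mean AUC into superior (A), good (B1/B2) and poor (C)
groups.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, squareform
from sklearn.cluster import KMeans

from .datamodel import PeakTable, SampleMetadata
from .evaluate import (
    DEFAULT_SVM_GRID,
    EvaluationResult,
    evaluate_on_validation,
    select_features,
    train_svm_cv,
)
from .normalize import ALL_METHODS, POSITIVE_REQUIRED, apply_model, normalize

__all__ = [
    "SubsampleScheme",
    "MethodGrouping",
    "BenchmarkResult",
    "split_train_validation",
    "kmeans_subsample",
    "allocate_largest_remainder",
    "run_benchmark",
    "method_distance",
    "ward_cluster",
    "categorize",
    "report",
]

DEFAULT_FRACTIONS = tuple(np.round(np.arange(1, 11) * 0.1, 1))


@dataclass
class SubsampleScheme:
    """How sub-datasets of growing size are drawn from the training set."""

    fractions: tuple = DEFAULT_FRACTIONS
    kmeans_k: int = 10
    nested: bool = True
    seed: int = 0

    def class_counts(self, n_per_class: dict) -> list[dict]:
        """Per-fraction class counts preserving the training class ratio."""
        out = []
        for f in self.fractions:
            counts = {c: int(round(f * n)) for c, n in n_per_class.items()}
            if any(v < 1 for v in counts.values()):
                raise ValueError(f"fraction {f} leaves a class empty")
            out.append(counts)
        return out


def split_train_validation(
    table: PeakTable,
    meta: SampleMetadata,
    valid_frac: float | None = None,
    train_counts: dict | None = None,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified random split of the study samples; seed-reproducible.

    Either ``valid_frac`` (fraction of each class held out) or
    ``train_counts`` (mapping class -> training count, remainder validation)
    must be given.
    """
    meta.check_two_classes()
    rng = np.random.default_rng(seed)
    study = [s for s in meta.study_ids() if s in set(table.sample_ids)]
    labels = meta.labels(study)
    train_ids: list[str] = []
    valid_ids: list[str] = []
    for c in np.unique(labels):
        ids = [s for s, l in zip(study, labels) if l == c]
        perm = rng.permutation(len(ids))
        if train_counts is not None:
            n_train = int(train_counts[c])
            if n_train >= len(ids) or n_train < 1:
                raise ValueError(f"train count {n_train} infeasible for class {c!r} ({len(ids)})")
        else:
            if valid_frac is None:
                raise ValueError("give valid_frac or train_counts")
            n_valid = max(int(round(valid_frac * len(ids))), 1)
            n_train = len(ids) - n_valid
            if n_train < 1:
                raise ValueError(f"validation fraction leaves class {c!r} without training samples")
        train_ids.extend(ids[i] for i in perm[:n_train])
        valid_ids.extend(ids[i] for i in perm[n_train:])
    if not valid_ids:
        raise ValueError("empty validation set")
    return sorted(train_ids), sorted(valid_ids)


def allocate_largest_remainder(cluster_sizes: np.ndarray, n: int) -> np.ndarray:
    """Allocate n draws over clusters proportionally (largest remainder)."""
    sizes = np.asarray(cluster_sizes, dtype=float)
    if n > sizes.sum():
        raise ValueError("requested count exceeds available samples")
    quota = n * sizes / sizes.sum()
    base = np.floor(quota).astype(int)
    base = np.minimum(base, sizes.astype(int))
    short = n - base.sum()
    remainder = quota - np.floor(quota)
    # stable tie-break: larger remainder first, then larger cluster, then index
    order = np.lexsort((np.arange(len(sizes)), -sizes, -remainder))
    for idx in order:
        if short == 0:
            break
        if base[idx] < sizes[idx]:
            base[idx] += 1
            short -= 1
    if short != 0:
        raise ValueError("allocation failed")
    return base


def _cluster_features(x: np.ndarray) -> np.ndarray:
    """Sample coordinates for k-means: log scale, feature-standardized."""
    L = np.log2(np.clip(x, np.min(x[x > 0]) / 2 if (x > 0).any() else 1e-9, None))
    mu = L.mean(axis=1, keepdims=True)
    sd = L.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return ((L - mu) / sd).T  # samples x features


def kmeans_subsample(
    table: PeakTable,
    meta: SampleMetadata,
    train_ids: list[str],
    scheme: SubsampleScheme | None = None,
) -> list[list[str]]:
    """Draw one sample-ID set per fraction, stratified by per-class k-means.

    Each class is clustered with k-means; draws are spread over clusters
    proportionally to cluster size (largest-remainder rounding). With
    ``nested`` each fraction is a superset of the previous one: within every
    cluster the members are randomly ordered once and taken as prefixes, the
    cluster receiving each next draw being the one furthest below its quota.
    """
    scheme = scheme or SubsampleScheme()
    rng = np.random.default_rng(scheme.seed)
    labels = meta.labels(train_ids)
    classes = np.unique(labels)
    n_per_class = {c: int((labels == c).sum()) for c in classes}
    counts_per_fraction = scheme.class_counts(n_per_class)

    sub = table.select_samples(train_ids)
    coords = _cluster_features(np.nan_to_num(sub.intensities, nan=0.0))

    # per class: cluster assignment and a fixed random order within clusters
    class_orders: dict = {}
    for c in classes:
        idx = np.flatnonzero(labels == c)
        k = min(scheme.kmeans_k, len(idx))
        km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31 - 1)))
        assign = km.fit_predict(coords[idx])
        clusters = [idx[assign == g] for g in range(k)]
        clusters = [cl for cl in clusters if len(cl)]
        ordered = [rng.permutation(cl) for cl in clusters]
        class_orders[c] = ordered

    out: list[list[str]] = []
    prev: dict = {c: np.zeros(len(class_orders[c]), dtype=int) for c in classes}
    for counts in counts_per_fraction:
        chosen: list[str] = []
        for c in classes:
            ordered = class_orders[c]
            sizes = np.array([len(cl) for cl in ordered], dtype=float)
            n = counts[c]
            if n > sizes.sum():
                raise ValueError(f"requested {n} samples exceeds class size {int(sizes.sum())}")
            if scheme.nested:
                take = np.maximum(prev[c], 0).copy()
                while take.sum() < n:
                    deficit = sizes * (take.sum() + 1) / sizes.sum() - take
                    deficit[take >= sizes] = -np.inf
                    take[int(np.argmax(deficit))] += 1
                prev[c] = take
            else:
                take = allocate_largest_remainder(sizes, n)
            for cl, t in zip(ordered, take):
                if scheme.nested:
                    picks = cl[:t]
                else:
                    picks = rng.choice(cl, size=t, replace=False)
                chosen.extend(train_ids[i] for i in picks)
        out.append(sorted(chosen))
    return out


@dataclass
class BenchmarkResult:
    methods: list[str]
    fractions: list[float]
    sizes: list[int]
    auc_matrix: np.ndarray  # methods x fractions
    acc_matrix: np.ndarray
    cells: dict = field(default_factory=dict)  # (method, fraction) -> EvaluationResult
    errors: dict = field(default_factory=dict)  # (method, fraction) -> message
    train_ids: list[str] = field(default_factory=list)
    valid_ids: list[str] = field(default_factory=list)


def _method_params(method: str, pre_imputation_mask, table, sub_ids, method_params) -> dict:
    params = dict(method_params.get(method, {}))
    if method in POSITIVE_REQUIRED:
        params.setdefault("nonpositive", "half_min")
    if method == "mstus" and pre_imputation_mask is not None and "shared_mask" not in params:
        idx = table.sample_index(sub_ids)
        params["shared_mask"] = pre_imputation_mask[:, idx]
    return params


def run_benchmark(
    table: PeakTable,
    meta: SampleMetadata,
    methods: list[str] | None = None,
    scheme: SubsampleScheme | None = None,
    valid_frac: float = 0.1,
    train_counts: dict | None = None,
    svm_grid: dict | None = None,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    n_components: int = 2,
    pre_imputation_mask: np.ndarray | None = None,
    method_params: dict | None = None,
    seed: int = 0,
    out_dir: str | None = None,
) -> BenchmarkResult:
    """Score every (method, sub-dataset) cell on one fixed validation set.

    The table must be preprocessed (imputed, complete). One seed governs the
    split, the subsampling and the CV folds. Per-cell failures are recorded
    and the run continues; with ``out_dir`` finished cells are cached on disk
    and reused on re-runs.
    """
    methods = list(methods or ALL_METHODS)
    scheme = scheme or SubsampleScheme(seed=seed)
    method_params = method_params or {}
    svm_grid = svm_grid or DEFAULT_SVM_GRID

    train_ids, valid_ids = split_train_validation(
        table, meta, valid_frac=valid_frac if train_counts is None else None,
        train_counts=train_counts, seed=seed,
    )
    subsets = kmeans_subsample(table, meta, train_ids, scheme)
    valid_table = table.select_samples(valid_ids)
    valid_labels = meta.labels(valid_ids)

    cache_dir = None
    if out_dir is not None:
        cache_dir = os.path.join(out_dir, "cells")
        os.makedirs(cache_dir, exist_ok=True)

    n_m, n_f = len(methods), len(scheme.fractions)
    auc = np.full((n_m, n_f), np.nan)
    acc = np.full((n_m, n_f), np.nan)
    cells: dict = {}
    errors: dict = {}
    for fi, (frac, sub_ids) in enumerate(zip(scheme.fractions, subsets)):
        sub_table = table.select_samples(sub_ids)
        sub_labels = meta.labels(sub_ids)
        for mi, method in enumerate(methods):
            key = (method, float(frac))
            cache_path = (
                os.path.join(cache_dir, f"{method}_{frac:g}.json") if cache_dir else None
            )
            if cache_path and os.path.exists(cache_path):
                with open(cache_path) as fh:
                    res = EvaluationResult.from_dict(json.load(fh))
                cells[key] = res
                auc[mi, fi] = res.auc
                acc[mi, fi] = res.acc
                continue
            try:
                res = _run_cell(
                    method, sub_table, sub_labels, valid_table, valid_labels,
                    _method_params(method, pre_imputation_mask, table, sub_ids, method_params),
                    svm_grid, vip_threshold, p_threshold, n_components, seed,
                    subset_size=len(sub_ids),
                )
            except Exception as exc:  # cell failure must not kill the sweep
                errors[key] = f"{type(exc).__name__}: {exc}"
                continue
            cells[key] = res
            auc[mi, fi] = res.auc
            acc[mi, fi] = res.acc
            if cache_path:
                with open(cache_path, "w") as fh:
                    json.dump(res.to_dict(), fh)
    sizes = [len(s) for s in subsets]
    return BenchmarkResult(
        methods=methods,
        fractions=[float(f) for f in scheme.fractions],
        sizes=sizes,
        auc_matrix=auc,
        acc_matrix=acc,
        cells=cells,
        errors=errors,
        train_ids=train_ids,
        valid_ids=valid_ids,
    )


def _run_cell(
    method, sub_table, sub_labels, valid_table, valid_labels, params,
    svm_grid, vip_threshold, p_threshold, n_components, seed, subset_size,
) -> EvaluationResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train_norm, model = normalize(sub_table, method, **params)
        apply_params = {"nonpositive": "half_min"} if method in POSITIVE_REQUIRED else {}
        valid_norm = apply_model(valid_table, model, **apply_params)
        selected = select_features(
            train_norm, sub_labels, vip_threshold=vip_threshold, p_threshold=p_threshold,
            n_components=n_components, fallback="top_k",
        )
        fpos = {f: i for i, f in enumerate(train_norm.feature_ids)}
        idx = np.array([fpos[f] for f in selected], dtype=int)
        clf, _ = train_svm_cv(train_norm.values[idx], sub_labels, grid=svm_grid, seed=seed)
        vpos = {f: i for i, f in enumerate(valid_norm.feature_ids)}
        vidx = np.array([vpos[f] for f in selected], dtype=int)
        return evaluate_on_validation(
            clf, valid_norm.values[vidx], valid_labels,
            selected_feature_ids=selected, method=method, subset_size=subset_size,
        )


# ---------------------------------------------------------------------------
# Distances, Ward clustering, categorization
# ---------------------------------------------------------------------------


def method_distance(auc_matrix: np.ndarray, metric: str = "manhattan") -> np.ndarray:
    """Pairwise distances between the methods' AUC vectors.

    Manhattan: sum_i |AUC_ai - AUC_bi|; Euclidean: the L2 analogue. Missing
    cells (failed runs) are imputed by the method's row mean with a warning.
    """
    if metric not in ("manhattan", "euclidean"):
        raise ValueError("metric must be 'manhattan' or 'euclidean'")
    m = np.asarray(auc_matrix, dtype=float).copy()
    if np.isnan(m).any():
        warnings.warn("missing AUC cells imputed by row mean for clustering", stacklevel=2)
        row_mean = np.nanmean(m, axis=1)
        rows, cols = np.where(np.isnan(m))
        m[rows, cols] = row_mean[rows]
    return cdist(m, m, metric="cityblock" if metric == "manhattan" else "euclidean")


def ward_cluster(distance_matrix: np.ndarray) -> np.ndarray:
    """Ward minimum-variance linkage (Lance-Williams on squared dissimilarities).

    Returns a SciPy linkage matrix; merge heights are non-decreasing.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or np.abs(np.diag(d)).max() > 1e-12:
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return hierarchy.linkage(squareform(d, checks=False), method="ward")


@dataclass
class MethodGrouping:
    """Dendrogram cut of the methods with A/B1/B2/C group labels."""

    methods: list[str]
    fractions: list[float]
    auc_matrix: np.ndarray
    distance_matrix: np.ndarray
    linkage: np.ndarray
    assignment: dict  # method -> "A" | "B1" | "B2" | "C"

    def groups(self) -> dict:
        out: dict[str, list[str]] = {"A": [], "B1": [], "B2": [], "C": []}
        for m in self.methods:
            out[self.assignment[m]].append(m)
        return out

    def to_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "fractions": list(self.fractions),
            "auc_matrix": np.asarray(self.auc_matrix).tolist(),
            "distance_matrix": np.asarray(self.distance_matrix).tolist(),
            "linkage": np.asarray(self.linkage).tolist(),
            "assignment": dict(self.assignment),
            "groups": self.groups(),
        }


def categorize(
    linkage: np.ndarray,
    auc_matrix: np.ndarray,
    methods: list[str],
    fractions: list[float] | None = None,
    distance_matrix: np.ndarray | None = None,
) -> MethodGrouping:
    """Cut the dendrogram at k=3 and rank clusters by mean AUC.

    The highest-mean cluster is group A (superior), the lowest C (poor). The
    middle cluster B splits into B1 (methods whose AUC reaches the top tertile
    of all methods on at least one sub-dataset size) and B2 (the rest).
    """
    m = np.asarray(auc_matrix, dtype=float)
    if len(methods) < 3:
        raise ValueError("k=3 cut requires at least 3 methods")
    labels = hierarchy.fcluster(linkage, t=3, criterion="maxclust")
    if len(set(labels)) < 3:
        raise ValueError("k=3 cut infeasible on this linkage")
    row_mean = np.nanmean(m, axis=1)
    cluster_ids = sorted(set(labels))
    cluster_mean = {c: row_mean[labels == c].mean() for c in cluster_ids}
    ranked = sorted(cluster_ids, key=lambda c: cluster_mean[c], reverse=True)
    tier_of = {ranked[0]: "A", ranked[1]: "B", ranked[2]: "C"}

    # top tertile per fraction: the best ceil(n/3) methods
    n_top = int(np.ceil(len(methods) / 3))
    in_top = np.zeros(len(methods), dtype=bool)
    for fi in range(m.shape[1]):
        col = m[:, fi]
        ok = ~np.isnan(col)
        if ok.sum() == 0:
            continue
        order = np.argsort(np.where(ok, col, -np.inf))[::-1]
        in_top[order[:n_top]] = True

    assignment = {}
    for i, meth in enumerate(methods):
        tier = tier_of[labels[i]]
        if tier == "B":
            tier = "B1" if in_top[i] else "B2"
        assignment[meth] = tier
    return MethodGrouping(
        methods=list(methods),
        fractions=list(fractions or range(1, m.shape[1] + 1)),
        auc_matrix=m,
        distance_matrix=(
            np.asarray(distance_matrix) if distance_matrix is not None else method_distance(m)
        ),
        linkage=np.asarray(linkage, dtype=float),
        assignment=assignment,
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def report(
    grouping: MethodGrouping,
    result: BenchmarkResult | None,
    out_dir: str,
    raw_table: PeakTable | None = None,
    normalized=None,
    figures: bool = True,
) -> str:
    """Write a markdown report: AUC heatmap table, groups, dendrogram, plots.

    Returns the path of the report file.
    """
    from .io import linkage_to_newick

    os.makedirs(out_dir, exist_ok=True)
    lines: list[str] = ["# Normalization benchmark report", ""]
    sizes = result.sizes if result is not None else [f"{f:g}" for f in grouping.fractions]
    lines.append(f"Methods evaluated: {len(grouping.methods)}; sub-dataset sizes: {len(sizes)}.")
    lines.append("")
    lines.append("## AUC by method and training size")
    lines.append("")
    header = "| Method | " + " | ".join(str(s) for s in sizes) + " |"
    lines.append(header)
    lines.append("|" + "---|" * (len(sizes) + 1))
    col_max = np.nanmax(grouping.auc_matrix, axis=0)
    col_min = np.nanmin(grouping.auc_matrix, axis=0)
    for i, meth in enumerate(grouping.methods):
        cells = []
        for j in range(grouping.auc_matrix.shape[1]):
            v = grouping.auc_matrix[i, j]
            if np.isnan(v):
                cells.append("-")
            elif v == col_max[j]:
                cells.append(f"**{v:.4f}**")  # blue end of the scale: column max
            elif v == col_min[j]:
                cells.append(f"_{v:.4f}_")  # red end: column min
            else:
                cells.append(f"{v:.4f}")
        lines.append("| " + meth + " | " + " | ".join(cells) + " |")
    lines.append("")
    lines.append("## Method groups")
    lines.append("")
    names = {
        "A": "Group A (superior performance)",
        "B1": "Group B1 (good, occasionally top-ranked)",
        "B2": "Group B2 (good, consistently mid-ranked)",
        "C": "Group C (poor performance)",
    }
    for g, members in grouping.groups().items():
        lines.append(f"### {names[g]}")
        lines.append("")
        lines.append(", ".join(members) if members else "(none)")
        lines.append("")
    lines.append("## Dendrogram (Newick)")
    lines.append("")
    newick = linkage_to_newick(grouping.linkage, grouping.methods)
    lines.append("```")
    lines.append(newick)
    lines.append("```")
    lines.append("")

    if result is not None and result.errors:
        lines.append("## Failed cells")
        lines.append("")
        for (meth, frac), msg in sorted(result.errors.items()):
            lines.append(f"- {meth} @ fraction {frac:g}: {msg}")
        lines.append("")

    if figures:
        try:
            fig_lines = _report_figures(grouping, result, out_dir, raw_table, normalized)
            lines.extend(fig_lines)
        except Exception as exc:  # plotting must never fail the run
            lines.append(f"(figures skipped: {exc})")

    path = os.path.join(out_dir, "report.md")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def _report_figures(grouping, result, out_dir, raw_table, normalized) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lines = ["## Figures", ""]
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(grouping.auc_matrix, aspect="auto", cmap="coolwarm_r")
    ax.set_yticks(range(len(grouping.methods)), grouping.methods, fontsize=7)
    sizes = result.sizes if result is not None else grouping.fractions
    ax.set_xticks(range(len(sizes)), [str(s) for s in sizes], fontsize=7)
    ax.set_xlabel("training size")
    fig.colorbar(im, ax=ax, label="AUC")
    fig.tight_layout()
    p = os.path.join(out_dir, "auc_heatmap.png")
    fig.savefig(p, dpi=120)
    plt.close(fig)
    lines += [f"![AUC heatmap](auc_heatmap.png)", ""]

    if result is not None and result.cells:
        fig, ax = plt.subplots(figsize=(6, 6))
        top = max(result.fractions)
        for (meth, frac), res in sorted(result.cells.items()):
            if frac == top:
                ax.plot(res.roc_points[:, 0], res.roc_points[:, 1], lw=1, label=meth)
        ax.plot([0, 1], [0, 1], color="grey", ls="--", lw=1)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=6)
        fig.tight_layout()
        p = os.path.join(out_dir, "roc_full_size.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        lines += ["![ROC at full training size](roc_full_size.png)", ""]

    if raw_table is not None and normalized is not None:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=False)
        with np.errstate(divide="ignore"):
            axes[0].boxplot(
                [np.log2(c[c > 0]) for c in raw_table.intensities.T], showfliers=False
            )
        axes[0].set_title("before normalization (log2)")
        vals = normalized.values
        axes[1].boxplot(list(vals.T), showfliers=False)
        axes[1].set_title(f"after {normalized.method}")
        for ax in axes:
            ax.set_xticks([])
        fig.tight_layout()
        p = os.path.join(out_dir, "boxplots.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        lines += ["![Intensity distributions before/after](boxplots.png)", ""]
    return lines
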