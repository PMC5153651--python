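"""Pre-processing chain: QC-based feature filtering, QC-anchored signal-drift
correction, and KNN missing-value imputation.

The chain runs filter -> drift-correct -> impute: filtering first removes
features that would poison neighbor distances, and drift is removed before
imputation so it cannot leak into imputed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datamodel import PeakTable, SampleMetadata

__all__ = ["PreprocessConfig", "filter_features", "drift_correct", "knn_impute", "mean_impute", "run"]


@dataclass
class PreprocessConfig:
    """Thresholds of the pre-processing chain.

    qc_detect_frac: minimum fraction of QC samples a feature must be
        detected in (features below are dropped).
    qc_rsd_max: maximum relative standard deviation (SD/mean) across QC
        samples; "large variation" features above it are dropped.
    knn_k: number of neighbor features used for imputation.
    loess_span: span of the local-linear drift fit per feature and batch.
    """

    qc_detect_frac: float = 0.2
    qc_rsd_max: float = 0.30
    knn_k: int = 10
    drift_correction: bool = True
    loess_span: float = 0.75

    def validate(self) -> None:
        if not 0.0 <= self.qc_detect_frac <= 1.0:
            raise ValueError("qc_detect_frac must lie in [0, 1]")
        if self.qc_rsd_max <= 0:
            raise ValueError("qc_rsd_max must be positive")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if not 0.0 < self.loess_span <= 1.0:
            raise ValueError("loess_span must lie in (0, 1]")


def filter_features(
    table: PeakTable, meta: SampleMetadata, cfg: PreprocessConfig | None = None
) -> tuple[PeakTable, list[tuple[str, str]]]:
    """Drop features under-detected or unstable across QC samples.

    Returns the filtered table and a log of (feature_id, reason) pairs.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    qc = meta.qc_ids()
    qc = [s for s in qc if s in table.sample_ids]
    if not qc:
        raise ValueError(
            "no QC samples in table: disable QC-based filtering or provide QC samples"
        )
    idx = table.sample_index(qc)
    qc_obs = ~table.missing_mask[:, idx]
    detect_frac = qc_obs.mean(axis=1)

    dropped: list[tuple[str, str]] = []
    keep = np.ones(table.n_features, dtype=bool)
    for i in range(table.n_features):
        if detect_frac[i] < cfg.qc_detect_frac:
            keep[i] = False
            dropped.append((table.feature_ids[i], f"detected in {detect_frac[i]:.0%} of QC samples"))
            continue
        vals = table.intensities[i, idx][qc_obs[i]]
        if vals.size >= 2:
            m = vals.mean()
            rsd = np.inf if m == 0 else vals.std(ddof=1) / m
            if rsd > cfg.qc_rsd_max:
                keep[i] = False
                dropped.append((table.feature_ids[i], f"QC RSD {rsd:.2f} > {cfg.qc_rsd_max:.2f}"))
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    if len(kept_ids) < 2:
        raise ValueError("fewer than 2 features survive QC filtering")
    return table.select_features(kept_ids), dropped


def drift_correct(
    table: PeakTable, meta: SampleMetadata, cfg: PreprocessConfig | None = None
) -> PeakTable:
    """QC-anchored within-batch signal-drift correction.

    Per feature and batch, a local-linear (loess) curve of QC intensity vs
    injection order is fit; every sample is divided by the curve value at its
    own injection order and rescaled so the batch QC median is preserved.
    Features with fewer than 4 QC observations in a batch pass through
    unchanged in that batch.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    meta.check_covers(table)
    orders = meta.injection_orders(table.sample_ids).astype(float)
    if np.isnan(orders).any():
        raise ValueError("missing injection order")
    batches = meta.batches(table.sample_ids)
    roles = meta.df.loc[table.sample_ids, "role"].to_numpy()
    is_qc = roles == "qc"
    if not is_qc.any():
        raise ValueError("drift correction requires QC samples with injection orders")

    x = table.intensities.copy()
    for b in np.unique(batches):
        in_batch = batches == b
        qc_cols = np.flatnonzero(in_batch & is_qc)
        all_cols = np.flatnonzero(in_batch)
        if qc_cols.size == 0:
            continue
        qc_orders = orders[qc_cols]
        batch_orders = orders[all_cols]
        for i in range(table.n_features):
            obs = ~table.missing_mask[i, qc_cols]
            if obs.sum() < 4:
                continue
            xo = qc_orders[obs]
            yo = table.intensities[i, qc_cols][obs]
            srt = np.argsort(xo)
            curve = sm.nonparametric.lowess(
                yo[srt], xo[srt], frac=cfg.loess_span, it=3, xvals=batch_orders
            )
            curve = np.asarray(curve, dtype=float)
            if np.isnan(curve).any():
                # robustness iterations can zero out every weight at small n
                curve = np.asarray(
                    sm.nonparametric.lowess(
                        yo[srt], xo[srt], frac=cfg.loess_span, it=0, xvals=batch_orders
                    ),
                    dtype=float,
                )
            if np.isnan(curve).any():
                continue
            floor = 0.05 * max(np.median(yo), 1e-12)
            curve = np.clip(curve, floor, None)
            ratio = x[i, all_cols] / curve
            qc_in_all = np.isin(all_cols, qc_cols)
            qc_ratio = ratio[qc_in_all]
            qc_ratio = qc_ratio[~np.isnan(qc_ratio)]
            qc_med_raw = np.nanmedian(table.intensities[i, qc_cols])
            denom = np.median(qc_ratio)
            if denom <= 0 or not np.isfinite(denom):
                continue
            x[i, all_cols] = ratio * (qc_med_raw / denom)
    np.clip(x, 0.0, None, out=x)
    x[table.missing_mask] = np.nan
    return PeakTable(list(table.feature_ids), list(table.sample_ids), x, table.missing_mask.copy())


def _feature_distances(c: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pairwise feature distances: RMS difference over co-observed samples."""
    obs = (~mask).astype(float)
    cz = np.where(mask, 0.0, c)
    sq = cz**2
    # sum over co-observed j of (c_i - c_k)^2, via masked matrix products
    co = obs @ obs.T
    cross = cz @ cz.T
    s1 = sq @ obs.T
    s2 = obs @ sq.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = (s1 + s2 - 2 * cross) / co
    d2[co == 0] = np.inf
    np.clip(d2, 0.0, None, out=d2)
    return np.sqrt(d2)


def knn_impute(table: PeakTable, k: int = 10) -> PeakTable:
    """Impute missing cells from the k nearest features on the centered log scale.

    Intensities are log2(1+x)-transformed and each feature centered by its
    observed mean; distances are RMS differences over co-observed samples.
    A missing cell is imputed as the target's observed log-mean plus the
    inverse-distance-weighted mean of the neighbors' deviations from their own
    means over the target's observed samples (so identical features impute
    exactly; zero-distance ties share uniform weights). Centering makes the
    neighbors contribute their co-variation rather than their absolute level,
    which intensity data need because feature levels span orders of magnitude.
    Observed cells are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if table.is_complete:
        return table.copy()
    mask = table.missing_mask
    if mask.all(axis=1).any():
        bad = [f for f, m in zip(table.feature_ids, mask.all(axis=1)) if m]
        raise ValueError(f"features with no observed values (filter first): {bad}")
    x = table.intensities
    with np.errstate(invalid="ignore"):
        L = np.log2(1.0 + x)
    row_mean = np.nanmean(L, axis=1)
    dist = _feature_distances(L - row_mean[:, None], mask)
    np.fill_diagonal(dist, np.inf)
    obs = ~mask

    out_log = L.copy()
    warned = False
    for i in np.flatnonzero(mask.any(axis=1)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            nm_i = np.nanmean(L[:, obs[i]], axis=1)  # neighbor means over target's observed cols
        order = np.argsort(dist[i], kind="stable")
        for j in np.flatnonzero(mask[i]):
            valid = obs[order, j] & np.isfinite(dist[i, order]) & np.isfinite(nm_i[order])
            candidates = order[valid]
            if candidates.size == 0:
                out_log[i, j] = nm_i[i]  # fall back to the feature mean
                continue
            if candidates.size < k and not warned:
                warnings.warn(
                    f"fewer than k={k} neighbors available for some cells; using all available",
                    stacklevel=2,
                )
                warned = True
            nb = candidates[:k]
            d = dist[i, nb]
            dev = L[nb, j] - nm_i[nb]
            if np.any(d == 0):
                out_log[i, j] = nm_i[i] + dev[d == 0].mean()
            else:
                w = 1.0 / d
                out_log[i, j] = nm_i[i] + float(np.dot(w, dev) / w.sum())
    out = x.copy()
    out[mask] = np.clip(2.0 ** out_log[mask] - 1.0, 0.0, None)
    return PeakTable(
        list(table.feature_ids),
        list(table.sample_ids),
        out,
        np.zeros_like(mask),
    )


def mean_impute(table: PeakTable) -> PeakTable:
    """Feature-mean imputation, used only as a comparison baseline."""
    x = table.intensities.copy()
    means = np.nanmean(x, axis=1)
    rows, cols = np.where(table.missing_mask)
    x[rows, cols] = means[rows]
    return PeakTable(list(table.feature_ids), list(table.sample_ids), x, np.zeros_like(table.missing_mask))


def run(
    table: PeakTable, meta: SampleMetadata, cfg: PreprocessConfig | None = None
) -> tuple[PeakTable, dict]:
    """Full chain: filter -> drift-correct -> impute. Returns table + log dict."""
    cfg = cfg or PreprocessConfig()
    filtered, dropped = filter_features(table, meta, cfg)
    pre_mask = filtered.missing_mask.copy()
    if cfg.drift_correction:
        filtered = drift_correct(filtered, meta, cfg)
    imputed = knn_impute(filtered, cfg.knn_k)
    log = {
        "n_dropped": len(dropped),
        "dropped": dropped,
        "n_imputed_cells": int(pre_mask.sum()),
        "pre_imputation_mask": pre_mask,
    }
    return imputed, log
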