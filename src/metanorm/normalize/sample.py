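"""Sample-wise normalization: removal of dilution, baseline and distributional
differences between samples.

All functions take an imputed (complete) PeakTable and return
(NormalizedTable, ReferenceModel). Passing a previously fitted model applies
its frozen reference to the given samples, which is how held-out validation
data are normalized without information leakage.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import make_smoothing_spline
from scipy.linalg import helmert

from ..datamodel import NormalizedTable, PeakTable, Scale
from . import ReferenceModel

__all__ = [
    "linear_baseline",
    "pqn",
    "mstus",
    "quantile_normalize",
    "cyclic_loess",
    "contrast_normalize",
    "cubic_splines",
    "li_wong",
]


def _matrix(table: PeakTable) -> np.ndarray:
    x = table.intensities
    if np.isnan(x).any():
        raise ValueError("normalization requires an imputed (complete) table")
    return np.array(x, dtype=float)


def _positive(x: np.ndarray, table: PeakTable, method: str, policy: str) -> np.ndarray:
    """Enforce positivity; 'half_min' replaces non-positive cells by half the
    smallest positive value in the table."""
    if (x > 0).all():
        return x
    if policy == "half_min":
        pos = x[x > 0]
        if pos.size == 0:
            raise ValueError(f"{method}: no positive values in table")
        eps = 0.5 * pos.min()
        out = x.copy()
        out[out <= 0] = eps
        return out
    rows, cols = np.where(x <= 0)
    cells = [(table.feature_ids[r], table.sample_ids[c]) for r, c in zip(rows[:5], cols[:5])]
    raise ValueError(f"{method} requires positive intensities; offending cells include {cells}")


def _result(table: PeakTable, values: np.ndarray, method: str) -> NormalizedTable:
    return NormalizedTable(list(table.feature_ids), list(table.sample_ids), values, method, Scale.RAW)


def _dedupe_xy(xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse duplicate x values, averaging their y values."""
    ux, inv = np.unique(xs, return_inverse=True)
    uy = np.bincount(inv, weights=ys) / np.bincount(inv)
    return ux, uy


def piecewise_map(v: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Monotone piecewise-linear map through (xs, ys) with linear end extension."""
    xs, ys = _dedupe_xy(np.asarray(xs, float), np.asarray(ys, float))
    if xs.size == 1:
        return np.full_like(np.asarray(v, float), ys[0])
    out = np.interp(v, xs, ys)
    s0 = (ys[1] - ys[0]) / (xs[1] - xs[0])
    s1 = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    v = np.asarray(v, dtype=float)
    left = v < xs[0]
    right = v > xs[-1]
    out[left] = ys[0] + s0 * (v[left] - xs[0])
    out[right] = ys[-1] + s1 * (v[right] - xs[-1])
    return out


# ---------------------------------------------------------------------------
# Linear baseline scaling
# ---------------------------------------------------------------------------

def linear_baseline(table: PeakTable, model: ReferenceModel | None = None):
    """Scale each sample so its mean matches the mean of the median baseline.

    baseline b_i = median_j x_ij; factor s_j = mean(b) / mean(x_.j).
    """
    x = _matrix(table)
    col_means = x.mean(axis=0)
    if np.any(col_means == 0):
        bad = [table.sample_ids[j] for j in np.flatnonzero(col_means == 0)]
        raise ValueError(f"zero sample mean for {bad}")
    if model is None:
        baseline = np.median(x, axis=1)
        mean_b = float(baseline.mean())
        model = ReferenceModel(
            "linear_baseline",
            {"mean_baseline": mean_b, "baseline": baseline},
            list(table.sample_ids),
        )
    else:
        mean_b = float(model.payload["mean_baseline"])
    factors = mean_b / col_means
    return _result(table, x * factors[None, :], "linear_baseline"), model


# ---------------------------------------------------------------------------
# Probabilistic quotient normalization
# ---------------------------------------------------------------------------

def pqn(table: PeakTable, pre_integral: bool = True, model: ReferenceModel | None = None):
    """Divide each sample by its most probable dilution: the median of the
    feature-wise quotients against a median reference spectrum.

    With ``pre_integral`` each sample is first total-sum normalized to 100.
    """
    x = _matrix(table)
    totals = x.sum(axis=0)
    if model is not None:
        pre_integral = bool(model.payload["pre_integral"])
    if pre_integral:
        if np.any(totals == 0):
            raise ValueError("zero sample total in integral step")
        work = x * (100.0 / totals[None, :])
    else:
        work = x
    if model is None:
        reference = np.median(work, axis=1)
        if np.any(reference == 0):
            bad = [table.feature_ids[i] for i in np.flatnonzero(reference == 0)][:5]
            raise ValueError(f"zero median reference for features {bad}")
        model = ReferenceModel(
            "pqn", {"reference": reference, "pre_integral": pre_integral}, list(table.sample_ids)
        )
    reference = np.asarray(model.payload["reference"], dtype=float)
    quotients = work / reference[:, None]
    d = np.median(quotients, axis=0)
    if np.any(d <= 0):
        raise ValueError("non-positive dilution estimate")
    out = work / d[None, :]
    # effective per-sample divisor on the original intensity scale
    eff = d * (totals / 100.0) if pre_integral else d
    model.payload["dilution_factors"] = {s: float(v) for s, v in zip(table.sample_ids, eff)}
    return _result(table, out, "pqn"), model


# ---------------------------------------------------------------------------
# MS total useful signal
# ---------------------------------------------------------------------------

def mstus(
    table: PeakTable,
    shared_mask: np.ndarray | None = None,
    rescale: bool = True,
    model: ReferenceModel | None = None,
):
    """Divide each sample by the total signal of features shared by all samples.

    "Shared" is decided on the pre-imputation missing mask (features with zero
    missing entries); pass it via ``shared_mask`` when normalizing an imputed
    table. With ``rescale`` the output is multiplied by the mean total so it
    stays on the intensity scale.
    """
    x = _matrix(table)
    if model is None:
        mask = table.missing_mask if shared_mask is None else np.asarray(shared_mask, bool)
        shared = ~mask.any(axis=1)
        if not shared.any():
            raise ValueError("no features shared by all samples")
        shared_ids = [f for f, s in zip(table.feature_ids, shared) if s]
        totals = x[shared].sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("zero shared-feature total")
        model = ReferenceModel(
            "mstus",
            {
                "shared_features": shared_ids,
                "mean_total": float(totals.mean()) if rescale else 1.0,
                "rescale": rescale,
            },
            list(table.sample_ids),
        )
    shared_ids = list(model.payload["shared_features"])
    pos = {f: i for i, f in enumerate(table.feature_ids)}
    idx = np.array([pos[f] for f in shared_ids if f in pos], dtype=int)
    if idx.size == 0:
        raise ValueError("none of the stored shared features present in table")
    totals = x[idx].sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("zero shared-feature total")
    scale = float(model.payload["mean_total"]) if model.payload.get("rescale", True) else 1.0
    return _result(table, x / totals[None, :] * scale, "mstus"), model


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(table: PeakTable, model: ReferenceModel | None = None):
    """Force every sample to share the mean-rank reference distribution.

    Ties receive the mean of the rank-means they span. Frozen application maps
    a new sample's empirical quantiles onto the stored reference distribution
    by interpolation.
    """
    x = _matrix(table)
    p, n = x.shape
    if model is None:
        reference = np.sort(x, axis=0).mean(axis=1)
        model = ReferenceModel("quantile", {"reference": reference}, list(table.sample_ids))
        ref = reference
        cum = np.concatenate([[0.0], np.cumsum(ref)])
        out = np.empty_like(x)
        for j in range(n):
            rmin = stats.rankdata(x[:, j], method="min").astype(int)
            rmax = stats.rankdata(x[:, j], method="max").astype(int)
            # tie-free cells take the rank-mean exactly; ties average their span
            span_mean = (cum[rmax] - cum[rmin - 1]) / (rmax - rmin + 1)
            out[:, j] = np.where(rmin == rmax, ref[rmin - 1], span_mean)
        return _result(table, out, "quantile"), model
    ref = np.asarray(model.payload["reference"], dtype=float)
    m = ref.size
    out = np.empty_like(x)
    for j in range(n):
        r = stats.rankdata(x[:, j], method="average")
        q = (r - 1.0) / (p - 1.0) if p > 1 else np.zeros_like(r)
        out[:, j] = np.interp(q * (m - 1.0), np.arange(m), ref)
    return _result(table, out, "quantile"), model


# ---------------------------------------------------------------------------
# Cyclic loess
# ---------------------------------------------------------------------------

def _lowess_fit(y: np.ndarray, x: np.ndarray, span: float, it: int = 3) -> np.ndarray:
    delta = 0.01 * np.ptp(x) if np.ptp(x) > 0 else 0.0
    return sm.nonparametric.lowess(y, x, frac=span, it=it, delta=delta, return_sorted=False)


def cyclic_loess(
    table: PeakTable,
    max_cycles: int = 3,
    span: float = 0.75,
    tol: float = 1e-3,
    nonpositive: str = "error",
    model: ReferenceModel | None = None,
):
    """Pairwise MA-plot loess normalization, cycled over all sample pairs.

    For each pair, the loess fit of M = log2 ratio against A = mean log2
    intensity is split evenly between the two samples. Frozen application
    adjusts each new sample against the stored mean log2 reference spectrum.
    """
    x = _positive(_matrix(table), table, "cyclic_loess", nonpositive)
    L = np.log2(x)
    if model is None:
        n = L.shape[1]
        for _ in range(max_cycles):
            max_adj = 0.0
            for j in range(n - 1):
                for k in range(j + 1, n):
                    M = L[:, j] - L[:, k]
                    A = 0.5 * (L[:, j] + L[:, k])
                    fit = _lowess_fit(M, A, span)
                    L[:, j] -= fit / 2.0
                    L[:, k] += fit / 2.0
                    max_adj = max(max_adj, float(np.abs(fit).max()) / 2.0)
            if max_adj < tol:
                break
        model = ReferenceModel(
            "cyclic_loess",
            {"reference": L.mean(axis=1), "span": span, "max_cycles": max_cycles},
            list(table.sample_ids),
        )
        return _result(table, 2.0**L, "cyclic_loess"), model
    ref = np.asarray(model.payload["reference"], dtype=float)
    span = float(model.payload.get("span", span))
    cycles = int(model.payload.get("max_cycles", max_cycles))
    for j in range(L.shape[1]):
        col = L[:, j]
        for _ in range(cycles):
            M = col - ref
            A = 0.5 * (col + ref)
            fit = _lowess_fit(M, A, span)
            col = col - fit
            if np.abs(fit).max() < tol:
                break
        L[:, j] = col
    return _result(table, 2.0**L, "cyclic_loess"), model


# ---------------------------------------------------------------------------
# Contrast normalization
# ---------------------------------------------------------------------------

def contrast_normalize(
    table: PeakTable,
    span: float = 0.75,
    nonpositive: str = "half_min",
    model: ReferenceModel | None = None,
):
    """Orthonormal-contrast loess normalization.

    Log intensities are rotated per feature by an orthonormal basis whose
    first axis is the overall level (1/sqrt(n), ..., 1/sqrt(n)); each of the
    n-1 contrast coordinates is loess-smoothed against the level coordinate
    and the fit subtracted, then the rotation is inverted. Non-positive cells
    are first replaced by half the smallest positive value (the configurable
    epsilon policy).
    """
    x = _positive(_matrix(table), table, "contrast", nonpositive)
    L = np.log2(x)
    if model is None:
        n = L.shape[1]
        if n < 3:
            raise ValueError("contrast normalization requires at least 3 samples")
        Q = helmert(n, full=True)  # orthonormal; first row 1/sqrt(n)
        Y = L @ Q.T
        for k in range(1, n):
            fit = _lowess_fit(Y[:, k], Y[:, 0], span)
            Y[:, k] -= fit
        L2 = Y @ Q
        model = ReferenceModel(
            "contrast",
            {"reference": L2.mean(axis=1), "span": span},
            list(table.sample_ids),
        )
        return _result(table, 2.0**L2, "contrast"), model
    # frozen application: smooth each sample's M against the stored level axis
    ref = np.asarray(model.payload["reference"], dtype=float)
    span = float(model.payload.get("span", span))
    for j in range(L.shape[1]):
        M = L[:, j] - ref
        A = 0.5 * (L[:, j] + ref)
        fit = _lowess_fit(M, A, span)
        L[:, j] -= fit
    return _result(table, 2.0**L, "contrast"), model


# ---------------------------------------------------------------------------
# Cubic splines (quantile-anchored smoothing-spline baseline normalization)
# ---------------------------------------------------------------------------

def cubic_splines(
    table: PeakTable,
    n_quantiles: int = 100,
    n_iter: int = 3,
    nonpositive: str = "error",
    model: ReferenceModel | None = None,
):
    """Map each sample onto the geometric-mean baseline through cubic
    smoothing splines fitted to paired quantiles on the log scale, iterated
    with rotated quantile offsets."""
    x = _positive(_matrix(table), table, "cubic_splines", nonpositive)
    L = np.log2(x)
    if model is None:
        baseline = L.mean(axis=1)  # log2 of geometric mean
        model = ReferenceModel(
            "cubic_splines",
            {"baseline": baseline, "n_quantiles": n_quantiles, "n_iter": n_iter},
            list(table.sample_ids),
        )
    baseline = np.asarray(model.payload["baseline"], dtype=float)
    nq = int(model.payload.get("n_quantiles", n_quantiles))
    iters = int(model.payload.get("n_iter", n_iter))
    out = np.empty_like(L)
    for j in range(L.shape[1]):
        v = L[:, j].copy()
        for t in range(iters):
            probs = (np.arange(nq) + (t + 0.5) / iters) / nq
            xq = np.quantile(v, probs)
            yq = np.quantile(baseline, probs)
            ux, uy = _dedupe_xy(xq, yq)
            if ux.size < 4:
                v = piecewise_map(v, ux, uy)
                continue
            spline = make_smoothing_spline(ux, uy)
            inside = (v >= ux[0]) & (v <= ux[-1])
            w = np.empty_like(v)
            w[inside] = spline(v[inside])
            # linear extension using boundary derivatives
            d0, d1 = float(spline.derivative()(ux[0])), float(spline.derivative()(ux[-1]))
            lo = v < ux[0]
            hi = v > ux[-1]
            w[lo] = float(spline(ux[0])) + d0 * (v[lo] - ux[0])
            w[hi] = float(spline(ux[-1])) + d1 * (v[hi] - ux[-1])
            v = w
        out[:, j] = v
    return _result(table, 2.0**out, "cubic_splines"), model


# ---------------------------------------------------------------------------
# Li-Wong (rank-invariant-set non-linear baseline normalization)
# ---------------------------------------------------------------------------

def _invariant_set(
    sample: np.ndarray,
    baseline: np.ndarray,
    prd_threshold: float,
    min_invariant: int,
    adapt: bool,
    max_rounds: int = 50,
) -> tuple[np.ndarray, float]:
    p = sample.size
    threshold = prd_threshold
    while True:
        idx = np.arange(p)
        for _ in range(max_rounds):
            rs = stats.rankdata(sample[idx])
            rb = stats.rankdata(baseline[idx])
            prd = np.abs(rs - rb) / idx.size
            keep = prd < threshold
            if keep.sum() == idx.size:
                break
            if keep.sum() < min_invariant:
                idx = idx[keep] if keep.sum() > 0 else idx[:0]
                break
            idx = idx[keep]
        if idx.size >= min_invariant:
            return idx, threshold
        if not adapt:
            raise ValueError(
                f"rank-invariant set has {idx.size} < {min_invariant} features; "
                f"increase prd_threshold (currently {threshold})"
            )
        threshold *= 2.0
        if threshold > 2.0:
            raise ValueError("could not build a rank-invariant set of sufficient size")


def li_wong(
    table: PeakTable,
    prd_threshold: float = 0.005,
    span: float = 0.4,
    min_invariant: int = 10,
    adapt: bool = True,
    nonpositive: str = "error",
    model: ReferenceModel | None = None,
):
    """Normalize each sample onto a baseline sample through a loess curve
    fitted on an iteratively refined rank-invariant feature set.

    The baseline is the sample whose total intensity is the median of totals.
    With ``adapt`` the proportional-rank-difference threshold is doubled (with
    a warning) until the invariant set reaches ``min_invariant`` features,
    which desk-scale feature counts routinely require.
    """
    x = _positive(_matrix(table), table, "li_wong", nonpositive)
    L = np.log2(x)
    if model is None:
        totals = x.sum(axis=0)
        base_idx = int(np.argsort(totals, kind="stable")[(len(totals) - 1) // 2])
        model = ReferenceModel(
            "li_wong",
            {
                "baseline": L[:, base_idx],
                "baseline_sample": table.sample_ids[base_idx],
                "prd_threshold": prd_threshold,
                "span": span,
                "min_invariant": min_invariant,
            },
            list(table.sample_ids),
        )
    baseline = np.asarray(model.payload["baseline"], dtype=float)
    threshold = float(model.payload.get("prd_threshold", prd_threshold))
    span = float(model.payload.get("span", span))
    min_invariant = int(model.payload.get("min_invariant", min_invariant))
    out = np.empty_like(L)
    adapted = threshold
    for j in range(L.shape[1]):
        col = L[:, j]
        if np.array_equal(col, baseline):
            out[:, j] = col
            continue
        idx, used = _invariant_set(col, baseline, threshold, min_invariant, adapt)
        if used != threshold:
            adapted = max(adapted, used)
        xs = col[idx]
        ys = baseline[idx]
        srt = np.argsort(xs, kind="stable")
        fitted = sm.nonparametric.lowess(ys[srt], xs[srt], frac=span, it=3, return_sorted=True)
        out[:, j] = piecewise_map(col, fitted[:, 0], fitted[:, 1])
    if adapted != threshold:
        warnings.warn(
            f"li_wong: prd_threshold adapted from {threshold} to {adapted} to reach "
            f"{min_invariant} invariant features",
            stacklevel=2,
        )
    return _result(table, 2.0**out, "li_wong"), model
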